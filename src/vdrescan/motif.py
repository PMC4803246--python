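"""Position-weight-matrix construction and double-stranded motif scanning.

The scanning model is the classical one used for transcription-factor
binding-site prediction: a position frequency matrix (base counts per
motif column, e.g. a JASPAR PFM) is converted to a log-odds position
weight matrix against a background base composition, every window of the
target sequence is scored on both strands by summing per-column weights,
and hits are reported on a min-max normalised "relative score" scale
(0-100%) so that thresholds such as 70% or 80% are comparable across
matrices of different information content.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np

from .errors import DegenerateMatrixError, FormatError, WindowLengthError

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0,C=1,G=2,T=3; anything else -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


@dataclass(frozen=True)
class CountMatrix:
    """A position frequency matrix: base counts per motif column.

    ``counts`` has shape (4, L) with rows in fixed A, C, G, T order.
    """

    motif_id: str
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise FormatError(
                f"count matrix must have shape (4, L) with L >= 1, got {counts.shape}"
            )
        if (counts < 0).any():
            bad = BASES[int(np.argwhere(counts < 0)[0][0])]
            raise FormatError(f"negative count in row {bad!r}")
        if not (counts.sum(axis=0) > 0).any():
            raise FormatError("all columns have zero total count")
        object.__setattr__(self, "counts", counts.astype(float))

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class Pwm:
    """Log-odds (base 2) position weight matrix with its score range.

    weights[b, i] = log2( (count(b,i) + pc*bg_b) / ((N_i + pc) * bg_b) )
    where N_i is the total count of column i and pc the pseudocount mass.
    """

    motif_id: str
    weights: np.ndarray
    background: np.ndarray
    pseudocount: float
    max_score: float = field(init=False)
    min_score: float = field(init=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        object.__setattr__(self, "max_score", float(w.max(axis=0).sum()))
        object.__setattr__(self, "min_score", float(w.min(axis=0).sum()))

    @property
    def length(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class MotifHit:
    """One scored window.

    ``start`` is a 0-based offset on the forward strand of the scanned
    sequence; ``site`` is the matched subsequence in motif orientation
    (reverse-complemented for strand -1 hits).
    """

    sequence_id: str
    start: int
    strand: int
    raw_score: float
    relative_score: float
    site: str

    @property
    def end(self) -> int:
        """0-based exclusive end on the forward strand."""
        return self.start + len(self.site)


def read_jaspar(source: str | os.PathLike | TextIO) -> CountMatrix:
    """Read a JASPAR-style PFM.

    Accepts the bracketed 2016 JASPAR text layout (``>ID NAME`` header then
    four rows like ``A [ 4 19 0 ]``), a bare 4-row whitespace matrix in
    A, C, G, T row order, a path to such a file, or an open text stream.
    Rows are normalised to A, C, G, T order regardless of file order.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" not in s and os.path.exists(s):
            with open(s) as fh:
                text = fh.read()
        else:
            text = s
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty matrix input")

    motif_id = "PFM"
    if lines[0].startswith(">"):
        motif_id = lines[0][1:].strip().split()[0] if lines[0][1:].strip() else "PFM"
        lines = lines[1:]

    labelled = re.compile(r"^([ACGTacgt])\s*\[?\s*([-\d\s.]*?)\s*\]?$")
    rows: dict[str, list[float]] = {}
    bare_rows: list[list[float]] = []
    for ln in lines:
        m = labelled.match(ln)
        if m and m.group(1).upper() in _BASE_INDEX:
            base = m.group(1).upper()
            if base in rows:
                raise FormatError(f"duplicate row for base {base!r}")
            rows[base] = _parse_numbers(m.group(2), base)
        else:
            bare_rows.append(_parse_numbers(ln.strip("[] "), f"row {len(bare_rows) + 1}"))

    if rows:
        missing = [b for b in BASES if b not in rows]
        if missing:
            raise FormatError(f"missing row for base {missing[0]!r}")
        ordered = [rows[b] for b in BASES]
    else:
        if len(bare_rows) != 4:
            raise FormatError(
                f"expected 4 matrix rows (A,C,G,T order), found {len(bare_rows)}"
            )
        ordered = bare_rows

    lengths = {len(r) for r in ordered}
    if len(lengths) != 1:
        raise FormatError(f"ragged rows: lengths {sorted(len(r) for r in ordered)}")
    counts = np.array(ordered, dtype=float)
    if (counts < 0).any():
        bad = BASES[int(np.argwhere(counts < 0)[0][0])]
        raise FormatError(f"negative count in row {bad!r}")
    return CountMatrix(motif_id=motif_id, counts=counts)


def _parse_numbers(chunk: str, label) -> list[float]:
    toks = chunk.split()
    if not toks:
        raise FormatError(f"no counts in {label}")
    try:
        return [float(t) for t in toks]
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {label}: {exc}") from None


UNIFORM_BACKGROUND = np.full(4, 0.25)
DEFAULT_PSEUDOCOUNT = 0.8


def build_pwm(
    cm: CountMatrix,
    background: Iterable[float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Pwm:
    """Convert a count matrix to a log2-odds PWM.

    ``pseudocount`` is a total mass distributed across bases in proportion
    to the background, the convention used by the JASPAR/Biopython
    ecosystem. ``background`` must sum to 1; default uniform.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(list(background), float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities summing to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    totals = cm.counts.sum(axis=0)
    if pseudocount == 0 and (totals == 0).any():
        raise DegenerateMatrixError(
            "zero-total column with zero pseudocount: weights undefined"
        )
    with np.errstate(divide="ignore"):
        weights = np.log2(
            (cm.counts + pseudocount * bg[:, None])
            / ((totals + pseudocount)[None, :] * bg[:, None])
        )
    return Pwm(
        motif_id=cm.motif_id, weights=weights, background=bg, pseudocount=pseudocount
    )


def score_window(pwm: Pwm, window: str) -> float:
    """Raw log-odds score of one window of length L in motif orientation."""
    if len(window) != pwm.length:
        raise WindowLengthError(
            f"window length {len(window)} != motif length {pwm.length}"
        )
    codes = _encode(window)
    if (codes < 0).any():
        bad = window[int(np.argwhere(codes < 0)[0][0])]
        raise WindowLengthError(f"non-ACGT base {bad!r} in window")
    return float(pwm.weights[codes, np.arange(pwm.length)].sum())


def relative_score(pwm: Pwm, raw: float) -> float:
    """Min-max normalised score as a percentage of the achievable range."""
    span = pwm.max_score - pwm.min_score
    if span <= 0:
        raise DegenerateMatrixError("max_score == min_score: relative score undefined")
    return 100.0 * (raw - pwm.min_score) / span


def consensus(pwm: Pwm) -> str:
    """Per-column argmax base; ties resolved alphabetically (A<C<G<T)."""
    return "".join(BASES[i] for i in np.argmax(pwm.weights, axis=0))


def anti_consensus(pwm: Pwm) -> str:
    """Per-column argmin base (the worst achievable window)."""
    return "".join(BASES[i] for i in np.argmin(pwm.weights, axis=0))


def scan(
    pwm: Pwm,
    sequence: str,
    threshold: float = 70.0,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """Score every window of ``sequence`` on both strands and return hits
    with relative score >= ``threshold`` (percent), sorted by start, with
    forward-strand hits first at a shared start.

    Windows containing non-ACGT characters are skipped and counted in a
    log line. A sequence shorter than the motif yields an empty result.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be in [0, 100]")
    L = pwm.length
    n = len(sequence)
    if n < L:
        logger.warning(
            "sequence %s shorter than motif (%d < %d); no windows scanned",
            sequence_id, n, L,
        )
        return []
    span = pwm.max_score - pwm.min_score
    if span <= 0:
        raise DegenerateMatrixError("max_score == min_score: scanning undefined")

    codes = _encode(sequence.upper())
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info(
            "sequence %s: skipped %d windows containing non-ACGT bases",
            sequence_id, n_skipped,
        )

    cols = np.arange(L)
    # Reverse strand: score of revcomp(window) under W equals the forward
    # window scored under W reversed in both axes (complement = row flip).
    w_fwd = pwm.weights
    w_rev = pwm.weights[::-1, ::-1]
    hits: list[MotifHit] = []
    seq_upper = sequence.upper()
    for strand, w in ((1, w_fwd), (-1, w_rev)):
        raw = np.where(valid, w[np.clip(windows, 0, 3), cols].sum(axis=1), -np.inf)
        # raw lies in [min_score, max_score] by construction; clip the
        # float noise so boundary windows survive a 0 or 100 threshold
        rel = np.clip(100.0 * (raw - pwm.min_score) / span, 0.0, 100.0)
        rel[~valid] = -np.inf
        for start in np.nonzero(valid & (rel >= threshold))[0]:
            site = seq_upper[start : start + L]
            if strand == -1:
                site = reverse_complement(site)
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=int(start),
                    strand=strand,
                    raw_score=float(raw[start]),
                    relative_score=float(rel[start]),
                    site=site,
                )
            )
    hits.sort(key=lambda h: (h.start, -h.strand))
    return hits


def write_hits_tsv(hits: Iterable[MotifHit], path_or_handle) -> None:
    """Write hits as TSV with 1-based inclusive coordinates."""
    own = not hasattr(path_or_handle, "write")
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write("sequence_id\tstart\tend\tstrand\tsite\traw_score\trelative_score\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start + 1}\t{h.end}\t"
                f"{'+' if h.strand == 1 else '-'}\t{h.site}\t"
                f"{h.raw_score:.3f}\t{h.relative_score:.1f}\n"
            )
    finally:
        if own:
            fh.close()


def read_fasta(path_or_handle) -> dict[str, str]:
    """Read a multi-record FASTA; keys are the first word of each header."""
    from Bio import SeqIO

    if hasattr(path_or_handle, "read"):
        handle = path_or_handle
        records = SeqIO.parse(handle, "fasta")
        return {rec.id: str(rec.seq) for rec in records}
    with open(path_or_handle) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
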