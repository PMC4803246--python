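import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vdrescan.genemodel import GeneModel
from vdrescan.motif import CountMatrix, build_pwm
from vdrescan.simulate import SYNTHETIC_DR3_PFM, default_pwm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # immutable fixtures shared across generated examples
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def dr3_pwm():
    """The package's default DR3-style scoring model."""
    return default_pwm()


@pytest.fixture(scope="session")
def dr3_text():
    return SYNTHETIC_DR3_PFM


@pytest.fixture
def toy_cm():
    """Tiny 3-column count matrix with hand-checkable weights."""
    return CountMatrix(
        motif_id="TOY",
        counts=np.array(
            [
                [100, 25, 0],
                [0, 25, 0],
                [0, 25, 10],
                [0, 25, 90],
            ],
            dtype=float,
        ),
    )


@pytest.fixture
def toy_pwm(toy_cm):
    return build_pwm(toy_cm, pseudocount=0.8)


@pytest.fixture
def toy_model():
    """Gene model with exon1=[1500,1541), intron1=[1541,3541),
    exon2=[3541,3691), intron2=[3691,4691), exon3=[4691,4841)."""
    return GeneModel(
        contig_id="toy",
        exons=((1500, 1541), (3541, 3691), (4691, 4841)),
        translation_start=1500,
    )


def brute_force_scan(pwm, sequence):
    """Independent scanning oracle: score every window on both strands by
    direct per-base summation, no vectorisation or shared code paths."""
    from vdrescan.motif import BASES

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {b: i for i, b in enumerate(BASES)}
    L = pwm.weights.shape[1]
    out = []
    seq = sequence.upper()
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if any(b not in idx for b in window):
            continue
        fwd = sum(pwm.weights[idx[b], i] for i, b in enumerate(window))
        rc = "".join(comp[b] for b in reversed(window))
        rev = sum(pwm.weights[idx[b], i] for i, b in enumerate(rc))
        out.append((start, 1, fwd))
        out.append((start, -1, rev))
    return out
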