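"""Study orchestration: inclusion bookkeeping, motif inventory, variant
impacts, cohort association and expression, emitted as one report.

The configuration is a plain mapping (typically loaded from YAML) with
one section per stage; every configured stage either runs or the report
marks it "skipped". Any stage failure aborts the run with the stage
name while preserving the partial report written so far.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .cohort import (
    adjusted_association,
    dominant_ttest,
    hwe_exact,
    maf,
    read_cohort_tsv,
)
from .errors import ConfigError, ConsistencyError, StageError
from .genemodel import parse_cvariant, read_gene_model_tsv
from .impact import study_report
from .motif import build_pwm, read_fasta, read_jaspar
from .qpcr import read_plate_tsv, summarize_plate
from .simulate import (
    GeneFixtureConfig,
    simulate_cohort,
    simulate_gene_fixture,
    simulate_qpcr,
)

logger = logging.getLogger(__name__)


def apply_inclusion(recruited: int, exclusions: Mapping[str, int]) -> tuple[int, list]:
    """Subject bookkeeping: analyzed = recruited - sum of labeled exclusions.

    Returns the analyzed count and a ledger of (label, count, remaining)
    entries in application order. Raises if exclusions overdraw the
    recruited total at any step.
    """
    if recruited < 0:
        raise ConsistencyError("recruited count must be non-negative")
    remaining = recruited
    ledger = []
    for label, count in exclusions.items():
        if count < 0:
            raise ConsistencyError(f"negative exclusion count for {label!r}")
        remaining -= count
        if remaining < 0:
            raise ConsistencyError(
                f"exclusions exceed recruitment at {label!r} "
                f"({recruited} recruited)"
            )
        ledger.append({"label": label, "excluded": int(count),
                       "remaining": int(remaining)})
    return remaining, ledger


def _round6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    return x


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _stage(report: dict, name: str, fn, out_dir: Path | None):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        report[name] = {"status": "error", "error": str(exc)}
        if out_dir is not None:
            _write_report(report, out_dir)
        raise StageError(name, exc) from exc
    elapsed = time.perf_counter() - t0
    logger.info("stage=%s elapsed=%.3fs", name, elapsed)
    result["status"] = "ok"
    result["elapsed_s"] = elapsed
    report[name] = result
    return result


def _write_report(report: dict, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    payload = dict(report)
    for section in payload.values():
        if isinstance(section, dict):
            section.pop("elapsed_s", None)
    path.write_text(json.dumps(_round6(payload), indent=2, sort_keys=True) + "\n")
    return path


def run_study(
    config: Mapping[str, Any], out_dir=None, seed: int | None = None
) -> dict:
    """Run the configured stages in order and return the study report.

    Config sections: ``inclusion`` (recruited, exclusions), ``gene``
    (simulate or matrix/fasta/genemodel/variants files, threshold),
    ``cohort`` (simulate or file, covariates), ``expression`` (simulate
    or file, reference, control_dose). A section that is absent or has
    ``enabled: false`` is marked skipped. ``seed`` overrides
    ``config["seed"]`` and feeds every simulated input.
    """
    if not isinstance(config, Mapping):
        raise ConfigError("config must be a mapping")
    out = Path(out_dir) if out_dir is not None else None
    seed = seed if seed is not None else config.get("seed", 0)
    report: dict[str, Any] = {
        "provenance": {
            "package_version": __version__,
            "seed": int(seed),
            "config_sha256": hashlib.sha256(
                json.dumps(_round6(_plain(config)), sort_keys=True).encode()
            ).hexdigest()[:16],
            "input_digests": {},
        }
    }
    digests = report["provenance"]["input_digests"]

    for name in ("inclusion", "gene", "cohort", "expression"):
        section = config.get(name)
        if section is None or (
            isinstance(section, Mapping) and section.get("enabled") is False
        ):
            report[name] = {"status": "skipped"}
            continue
        if name == "inclusion":
            _stage(report, name, lambda s=section: _run_inclusion(s), out)
        elif name == "gene":
            _stage(
                report, name,
                lambda s=section: _run_gene(s, seed, out, digests), out,
            )
        elif name == "cohort":
            _stage(
                report, name,
                lambda s=section: _run_cohort(s, seed, digests), out,
            )
        else:
            _stage(
                report, name,
                lambda s=section: _run_expression(s, seed, digests), out,
            )

    if out is not None:
        _write_report(report, out)
    return report


def _plain(obj):
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _run_inclusion(section: Mapping) -> dict:
    recruited = int(section.get("recruited", 0))
    exclusions = dict(section.get("exclusions", {}))
    analyzed, ledger = apply_inclusion(recruited, exclusions)
    return {"recruited": recruited, "analyzed": analyzed, "ledger": ledger}


def _run_gene(section: Mapping, seed, out: Path | None, digests: dict) -> dict:
    threshold = float(section.get("threshold", 70.0))
    pad = section.get("pad")
    if section.get("source", "simulate") == "simulate":
        fixture = simulate_gene_fixture(
            GeneFixtureConfig(threshold=threshold), seed=seed
        )
        pwm = fixture.pwm
        reference = fixture.sequence
        model = fixture.model
        variants = [parse_cvariant(v) for v in fixture.variants]
        truth = fixture.truth
    else:
        for key in ("matrix", "fasta", "genemodel"):
            if key not in section:
                raise ConfigError(f"gene stage with file source needs {key!r}")
        pwm = build_pwm(read_jaspar(section["matrix"]))
        sequences = read_fasta(section["fasta"])
        model = read_gene_model_tsv(section["genemodel"])
        if model.contig_id not in sequences:
            raise ConfigError(
                f"contig {model.contig_id!r} not present in FASTA"
            )
        reference = sequences[model.contig_id]
        variant_lines = []
        if "variants" in section:
            variant_lines = [
                ln.strip()
                for ln in Path(section["variants"]).read_text().splitlines()
                if ln.strip() and not ln.startswith("#")
            ]
            digests[str(section["variants"])] = _digest(section["variants"])
        for key in ("matrix", "fasta", "genemodel"):
            p = Path(section[key])
            if p.exists():
                digests[str(p)] = _digest(p)
        variants = [parse_cvariant(v) for v in variant_lines]
        truth = None

    tables = study_report(
        pwm, reference, model, variants, threshold=threshold,
        window_pad=int(pad) if pad is not None else None,
    )
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        tables.inventory.to_csv(out / "vdre_inventory.tsv", sep="\t", index=False,
                                float_format="%.6g")
        tables.impacts.to_csv(out / "variant_impacts.tsv", sep="\t", index=False,
                              float_format="%.6g")
    result = {
        "threshold": threshold,
        "n_inventory_hits": int(len(tables.inventory)),
        "inventory": tables.inventory.to_dict(orient="records"),
        "impacts": tables.impacts.where(pd.notna(tables.impacts), None).to_dict(
            orient="records"
        ),
    }
    if truth is not None:
        result["truth"] = truth
    return result


def _run_cohort(section: Mapping, seed, digests: dict) -> dict:
    if section.get("source", "simulate") == "simulate":
        table, truth = simulate_cohort(
            n=int(section.get("n", 307)),
            maf=float(section.get("maf", 0.013)),
            effect=float(section.get("effect", -5.7)),
            noise_sd=float(section.get("noise_sd", 7.0)),
            seed=seed,
        )
    else:
        path = section["file"]
        table = read_cohort_tsv(path)
        digests[str(path)] = _digest(path)
        truth = None
    covariates = section.get("covariates", ["age", "sex", "rs2227589"])
    m = maf(table)
    result = {
        "n": int(len(table)),
        "maf": m.maf,
        "carriers": m.carriers,
        "het": m.het,
        "hom_minor": m.hom_minor,
        "hwe_p": hwe_exact(m.het, m.hom_minor, m.n_genotyped - m.carriers),
    }
    try:
        t = dominant_ttest(table)
        result["ttest"] = {
            "t_pooled": t.t_pooled, "p_pooled": t.p_pooled,
            "t_welch": t.t_welch, "p_welch": t.p_welch,
            "carrier_mean": t.group_carrier.mean,
            "noncarrier_mean": t.group_noncarrier.mean,
        }
        a = adjusted_association(table, covariates=covariates)
        result["adjusted"] = {
            "effect": a.effect, "se": a.se, "p": a.p, "n": a.n,
            "covariates": list(a.covariates),
        }
    except Exception as exc:
        from .errors import InsufficientDataError

        if not isinstance(exc, InsufficientDataError):
            raise
        result["ttest"] = {"status": "insufficient data", "detail": str(exc)}
        result["adjusted"] = {"status": "insufficient data"}
    if truth is not None:
        result["truth"] = truth
    return result


def _run_expression(section: Mapping, seed, digests: dict) -> dict:
    reference = section.get("reference", "ACTB")
    control_dose = float(section.get("control_dose", 0.0))
    if section.get("source", "simulate") == "simulate":
        plate, truth = simulate_qpcr(
            ct_noise_sd=float(section.get("ct_noise_sd", 0.15)),
            replicates=int(section.get("replicates", 6)),
            seed=seed,
            reference=reference,
        )
    else:
        path = section["file"]
        plate = read_plate_tsv(path)
        digests[str(path)] = _digest(path)
        truth = None
    summary = summarize_plate(plate, reference=reference, control_dose=control_dose)
    result = {
        "reference": reference,
        "control_dose": control_dose,
        "summary": summary.to_dict(orient="records"),
    }
    if truth is not None:
        result["truth"] = truth
    return result
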