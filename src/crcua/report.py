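"""Tabular report emission for the full reproduction.

Every table is written as CSV with full-precision numeric columns plus
separate ``display_*`` columns rounded to the published precision, so that
downstream checks never depend on display rounding. A JSON manifest records
the configuration checksum, package version, seeds and the structural variant
so that identical inputs yield byte-identical checksummed outputs (the
manifest's timestamp is excluded from the checksum contract).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from .conversions import BGN_PER_EUR
from .cua import ArmResult, DetectedCohort, IncrementalResult
from .markov import ModelConfig
from .psa import PSAResult

__all__ = [
    "incremental_frame",
    "psa_summary_frame",
    "dominance_summary",
    "config_checksum",
    "write_manifest",
]


def _display(x: float, nd: int = 2) -> float:
    return round(x, nd)


def incremental_frame(
    res_with: ArmResult,
    res_without: ArmResult,
    inc: IncrementalResult,
    scale: int = 1,
) -> pd.DataFrame:
    """Two-arm cost/QALY table with deltas, optionally scaled to a cohort."""
    rows = [
        {
            "arm": res_with.arm_label,
            "cost_eur": res_with.total_cost * scale,
            "cost_bgn": res_with.total_cost * scale * BGN_PER_EUR,
            "qaly": res_with.total_qaly * scale,
            "delta_cost_eur": inc.delta_cost * scale,
            "delta_qaly": inc.delta_qaly * scale,
            "classification": inc.classification,
            "icur_eur_per_qaly": inc.icur,
        },
        {
            "arm": res_without.arm_label,
            "cost_eur": res_without.total_cost * scale,
            "cost_bgn": res_without.total_cost * scale * BGN_PER_EUR,
            "qaly": res_without.total_qaly * scale,
            "delta_cost_eur": None,
            "delta_qaly": None,
            "classification": None,
            "icur_eur_per_qaly": None,
        },
    ]
    frame = pd.DataFrame(rows)
    for col, nd in (("cost_eur", 2), ("cost_bgn", 2), ("qaly", 2), ("delta_cost_eur", 2), ("delta_qaly", 2)):
        frame[f"display_{col}"] = frame[col].map(
            lambda x, nd=nd: None if pd.isna(x) else _display(float(x), nd)
        )
    return frame


def psa_summary_frame(result: PSAResult) -> pd.DataFrame:
    """One-row PSA summary: means, acceptability, quadrant shares."""
    m = result.means
    row = {
        "n_iterations": result.n_iterations,
        "wtp_eur_per_qaly": result.wtp,
        **{f"mean_{k}": v for k, v in m.items()},
        "acceptability": result.acceptability,
        **{f"quadrant_{k}": v for k, v in result.quadrant_shares.items()},
        "n_redraws": result.n_redraws,
        "n_clamped_draws": result.n_clamped,
    }
    return pd.DataFrame([row])


def dominance_summary(
    inc: IncrementalResult, cohort: DetectedCohort | None = None, psa: PSAResult | None = None
) -> str:
    """Human-readable verdict block for the incremental comparison."""
    lines = []
    if inc.classification == "dominant":
        lines.append(
            "The screening programme dominates no screening "
            "(lower costs and more QALYs)."
        )
    elif inc.classification == "dominated":
        lines.append("The screening programme is dominated by no screening.")
    elif inc.classification == "equivalent":
        lines.append("The two strategies are equivalent.")
    else:
        lines.append(f"ICUR: {inc.icur:,.2f} EUR/QALY.")
    lines.append(
        f"Per patient: delta cost {inc.delta_cost:,.2f} EUR "
        f"(BGN {inc.delta_cost * BGN_PER_EUR:,.2f}), delta QALY {inc.delta_qaly:+.2f}."
    )
    if cohort is not None:
        lines.append(
            f"Detected cohort: {cohort.n_detected} patients "
            f"({100 * cohort.detection_rate:.2f}% of {cohort.fit_positive_count:,} positives); "
            f"total {inc.delta_cost * cohort.n_detected:,.2f} EUR and "
            f"{inc.delta_qaly * cohort.n_detected:+,.2f} QALYs."
        )
    if psa is not None:
        lines.append(
            f"PSA: cost-effective at {psa.wtp:,.2f} EUR/QALY in "
            f"{100 * psa.acceptability:.1f}% of {psa.n_iterations} iterations."
        )
    return "\n".join(lines)


def config_checksum(config: ModelConfig) -> str:
    """SHA-256 over a canonical JSON dump of the model configuration."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_manifest(
    path: str | Path,
    config: ModelConfig,
    seeds: dict,
    outputs: list[str],
    timestamp: str | None = None,
) -> dict:
    """Write the run manifest; the timestamp is excluded when ``None``."""
    from . import __version__

    manifest = {
        "package": "crcua",
        "version": __version__,
        "config_checksum": config_checksum(config),
        "structural_variant": dataclasses.asdict(config.variant),
        "seeds": seeds,
        "outputs": sorted(outputs),
    }
    if timestamp is not None:
        manifest["timestamp"] = timestamp
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
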