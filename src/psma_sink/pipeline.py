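"""End-to-end orchestration: per-patient measurement and cohort reports.

``run_patient`` composes SUV conversion, the four organ placements and the
burden metrics into one tabular row; per-organ failures (missing mask,
organ too small) are recorded as missing values and the run continues, the
way a real cohort tolerates a splenectomy or an organ outside the field of
view.  ``run_cohort`` turns a per-patient table into the report bundle
(correlations, strata, organ summaries, scatter data) and optionally writes
tidy CSVs, a JSON report and plots.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import LesionSet, compute_burden
from .cohort_stats import run_cohort_analysis
from .suvcore import PETVolume, ScanMeta, to_suv
from .voi_placement import ORGANS, OrganRegion, place_and_measure

log = logging.getLogger("psma_sink")


@dataclass
class RunConfig:
    """Options threaded through a pipeline run."""

    per_component: bool = False      # one sphere per kidney/parotid side
    edge_margin_mm: float = 5.0
    flag_ratio: float = 2.0
    include_zero_tlv: bool = True
    log_base: float = 10.0
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_patient(pet: PETVolume, organ_masks: dict[str, np.ndarray | None],
                meta: ScanMeta, lesions: LesionSet | None = None,
                config: RunConfig | None = None,
                patient_id: str = "patient") -> dict:
    """Measure one patient; returns a flat row dict.

    ``organ_masks`` maps organ name to a binary mask (or None/absent for a
    missing organ).  The PET volume may be activity concentration (it is
    converted) or already SUV.
    """
    cfg = config or RunConfig()
    suv = to_suv(pet, meta) if pet.value_kind == "activity" else pet
    row: dict = {"patient_id": patient_id}
    for organ in ORGANS:
        mask = organ_masks.get(organ)
        if mask is None or not np.asarray(mask, dtype=bool).any():
            warnings.warn(f"organ {organ!r} missing for {patient_id}")
            row[f"suv_{organ}"] = np.nan
            continue
        try:
            res = place_and_measure(
                suv, OrganRegion(organ, mask, edge_margin_mm=cfg.edge_margin_mm),
                per_component=cfg.per_component, flag_ratio=cfg.flag_ratio)
        except ValueError as exc:
            warnings.warn(f"placement failed for {organ!r}: {exc}")
            row[f"suv_{organ}"] = np.nan
            continue
        log.info("%s/%s: center=%s n_candidates=%d score=%.4f median=%.4f",
                 patient_id, organ, res.center_index, res.n_candidates,
                 res.score, res.median_score)
        row[f"suv_{organ}"] = res.suv_mean
        row[f"center_{organ}"] = "/".join(f"{v:.1f}" for v in res.center_world_mm)
        row[f"n_candidates_{organ}"] = res.n_candidates
        row[f"flagged_{organ}"] = res.flagged
    if lesions is not None:
        b = compute_burden(suv, lesions, meta)
        row.update({"tlv_cm3": b.tlv_cm3, "tlu": b.tlu,
                    "pct_injected": b.pct_injected})
    return row


def run_cohort(table: pd.DataFrame, config: RunConfig | None = None,
               outdir: str | Path | None = None,
               plots: bool = False) -> dict:
    """Cohort report from a per-patient table; optionally write a bundle.

    The bundle contains ``report.json``, ``correlations.csv``,
    ``strata_summary.csv`` and a ``manifest.json`` with the package version
    and the configuration hash (identical hash implies identical numerical
    outputs for identical inputs).
    """
    cfg = config or RunConfig()
    report = run_cohort_analysis(table, include_zero_tlv=cfg.include_zero_tlv,
                                 log_base=cfg.log_base)
    for c in report["correlations"]:
        if c["n"] < 10:
            c["note"] = (c.get("note") or "") + " low-n"
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame(report["correlations"]).to_csv(
            outdir / "correlations.csv", index=False)
        strata_rows = []
        for label, entry in report["strata"].items():
            base = {"tlv_group": label, "n": entry["n"]}
            for organ, s in entry.get("organs", {}).items():
                strata_rows.append({**base, "organ": organ, **s})
            if not entry.get("organs"):
                strata_rows.append(base)
        pd.DataFrame(strata_rows).to_csv(outdir / "strata_summary.csv",
                                         index=False)
        manifest = {"package_version": __version__, "config": cfg.__dict__,
                    "config_hash": cfg.hash(),
                    "n_patients": report["n_patients"]}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if plots:
            _write_plots(table, report, outdir)
    return report


def _write_plots(table: pd.DataFrame, report: dict, outdir: Path) -> None:
    """Boxplots per organ/stratum and burden-vs-uptake scatter (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    organs = list(report["organ_summaries"])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([table[f"suv_{o}"].dropna() for o in organs],
               tick_labels=organs)
    ax.set_ylabel("SUVmean")
    fig.tight_layout()
    fig.savefig(outdir / "organ_boxplots.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(2, len(organs), figsize=(3 * len(organs), 6),
                             sharex="row")
    sc = report["scatter"]
    for j, o in enumerate(organs):
        axes[0, j].scatter(sc["tlv_cm3"], sc[f"suv_{o}"], s=4, alpha=0.4)
        axes[0, j].set_title(o)
        axes[1, j].scatter(sc["log_tlv"], sc[f"suv_{o}"], s=4, alpha=0.4)
    axes[0, 0].set_ylabel("SUVmean vs TLV")
    axes[1, 0].set_ylabel("SUVmean vs log10(TLV+1)")
    fig.tight_layout()
    fig.savefig(outdir / "scatter.png", dpi=120)
    plt.close(fig)
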