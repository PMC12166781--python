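"""Tumor proportion score (TPS) aggregation and AI-vs-pathologist concordance.

The TPS of a slide is the percentage of PD-L1 positive tumor cells among
all tumor cells::

    TPS = 100 * TC+ / (TC+ + TC-)

Other cells (OC) never enter the ratio.  A slide without any detected
tumor cells has an *undefined* TPS — reported as an explicit null, never
coerced to 0, since "no tumor cells found" must not masquerade as "PD-L1
negative".

The concordance layer compares AI scores against independent pathologist
scores: absolute discrepancies above 10 percentage points flag the
assessment for re-evaluation, scores are binarized at a clinical 20%
cutoff to measure decision-level accuracy, and per-rater correlation
coefficients summarize agreement on the continuous scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellCounts",
    "SlideScore",
    "ConcordanceConfig",
    "ConcordanceRecord",
    "compute_tps",
    "aggregate_patient",
    "flag_discrepancies",
    "cutoff_concordance",
    "correlation",
    "rater_summary",
    "reassessment_summary",
    "concordance_report",
]


@dataclass
class CellCounts:
    n_tcpos: int = 0
    n_tcneg: int = 0
    n_oc: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tcpos, self.n_tcneg, self.n_oc) < 0:
            raise ValueError("cell counts must be nonnegative")

    def __add__(self, other: "CellCounts") -> "CellCounts":
        return CellCounts(self.n_tcpos + other.n_tcpos,
                          self.n_tcneg + other.n_tcneg,
                          self.n_oc + other.n_oc)


@dataclass
class SlideScore:
    slide_id: str
    patient_id: str
    counts: CellCounts
    tps_percent: float | None = None

    def __post_init__(self) -> None:
        if self.tps_percent is None:
            self.tps_percent = compute_tps(self.counts)


@dataclass
class ConcordanceConfig:
    delta_pp: float = 10.0
    cutoff_percent: float = 20.0
    correlation: str = "pearson"          # or "spearman"
    patient_aggregation: str = "mean"     # or "max" / "per_slide"

    def __post_init__(self) -> None:
        if self.delta_pp <= 0:
            raise ValueError("delta_pp must be positive")
        if not 0 < self.cutoff_percent < 100:
            raise ValueError("cutoff_percent must lie in (0, 100)")


@dataclass
class ConcordanceRecord:
    """Paired AI/pathologist scores for one patient, with flag bookkeeping."""

    patient_id: str
    ai_tps: float
    pathologist_tps: list[float]
    flagged: list[bool] = field(default_factory=list)
    cutoff_labels: dict = field(default_factory=dict)
    reassessed: list[bool] = field(default_factory=list)
    revised_tps: list[float | None] = field(default_factory=list)


def compute_tps(counts: CellCounts) -> float | None:
    """TPS percentage, or None when the slide holds no tumor cells."""
    denom = counts.n_tcpos + counts.n_tcneg
    if denom == 0:
        return None
    return 100.0 * counts.n_tcpos / denom


def aggregate_patient(slide_scores: list[SlideScore],
                      cfg: ConcordanceConfig | None = None) -> float | None:
    """Patient-level TPS from one or more slides.

    Defaults to the arithmetic mean of the defined per-slide TPS values
    (``max`` is available as an alternative); per-slide values stay
    available on the inputs.  All-undefined slides give None.
    """
    cfg = cfg or ConcordanceConfig()
    if not slide_scores:
        raise ValueError("at least one slide required")
    vals = [s.tps_percent for s in slide_scores if s.tps_percent is not None]
    if not vals:
        return None
    if cfg.patient_aggregation == "max":
        return float(max(vals))
    return float(np.mean(vals))


def flag_discrepancies(ai: float, raters: list[float],
                       cfg: ConcordanceConfig | None = None) -> list[bool]:
    """Per-rater flags: |ai - rater| strictly greater than delta_pp."""
    cfg = cfg or ConcordanceConfig()
    return [abs(ai - r) > cfg.delta_pp for r in raters]


def cutoff_concordance(ai: list[float], rater: list[float],
                       cfg: ConcordanceConfig | None = None) -> tuple[float, int]:
    """Accuracy after binarizing both score lists at the clinical cutoff.

    Scores at or above the cutoff count as positive.  Returns the accuracy
    percentage and the number of discordant cases.
    """
    cfg = cfg or ConcordanceConfig()
    ai, rater = np.asarray(ai, dtype=float), np.asarray(rater, dtype=float)
    if ai.shape != rater.shape:
        raise ValueError("ai and rater score lists must have equal length")
    if ai.size == 0:
        raise ValueError("need at least one case")
    agree = (ai >= cfg.cutoff_percent) == (rater >= cfg.cutoff_percent)
    discordant = int((~agree).sum())
    return 100.0 * agree.mean(), discordant


def correlation(ai: list[float], rater: list[float],
                cfg: ConcordanceConfig | None = None) -> float | None:
    """Correlation between AI and one rater (Pearson by default)."""
    cfg = cfg or ConcordanceConfig()
    ai, rater = np.asarray(ai, dtype=float), np.asarray(rater, dtype=float)
    if ai.size < 3:
        raise ValueError("need at least 3 paired scores")
    if np.std(ai) == 0 or np.std(rater) == 0:
        return None
    if cfg.correlation == "spearman":
        return float(stats.spearmanr(ai, rater).statistic)
    return float(stats.pearsonr(ai, rater).statistic)


def rater_summary(ai: list[float], raters: dict[str, list[float]],
                  cfg: ConcordanceConfig | None = None) -> dict:
    """Per-rater correlation and cutoff accuracy, plus their means."""
    cfg = cfg or ConcordanceConfig()
    out = {"per_rater": {}, "mean_correlation": None, "mean_cutoff_accuracy": None}
    corrs, accs = [], []
    for rid, scores in raters.items():
        r = correlation(ai, scores, cfg)
        acc, disc = cutoff_concordance(ai, scores, cfg)
        out["per_rater"][rid] = {"correlation": r, "cutoff_accuracy": acc,
                                 "discordant": disc}
        if r is not None:
            corrs.append(r)
        accs.append(acc)
    if corrs:
        out["mean_correlation"] = float(np.mean(corrs))
    if accs:
        out["mean_cutoff_accuracy"] = float(np.mean(accs))
    return out


def reassessment_summary(records: list[ConcordanceRecord]) -> dict:
    """Counts of flagged / re-evaluated assessments over patients x raters."""
    n_raters = {len(r.pathologist_tps) for r in records}
    if len(n_raters) > 1:
        raise ValueError("inconsistent rater count across records")
    n_patients_flagged = sum(any(r.flagged) for r in records)
    n_flagged = sum(sum(r.flagged) for r in records)
    total = sum(len(r.pathologist_tps) for r in records)
    n_changed = n_unchanged = 0
    for r in records:
        for k, re_eval in enumerate(r.reassessed):
            if not re_eval:
                continue
            revised = r.revised_tps[k] if k < len(r.revised_tps) else None
            if revised is not None and revised != r.pathologist_tps[k]:
                n_changed += 1
            else:
                n_unchanged += 1
    return {
        "n_patients": len(records),
        "n_assessments": total,
        "n_patients_flagged": n_patients_flagged,
        "n_assessments_flagged": n_flagged,
        "pct_assessments": 100.0 * n_flagged / total if total else 0.0,
        "n_changed": n_changed,
        "n_unchanged": n_unchanged,
    }


def concordance_report(ai_by_patient: dict[str, float],
                       pathologist_table: pd.DataFrame,
                       cfg: ConcordanceConfig | None = None
                       ) -> tuple[pd.DataFrame, dict, list[ConcordanceRecord]]:
    """Build the full per-assessment concordance table and summary.

    ``pathologist_table`` needs columns patient_id, rater_id, tps and
    optionally revised_tps.  Returns the long-format report (one row per
    patient x rater), the JSON-ready summary dict, and the per-patient
    records.
    """
    cfg = cfg or ConcordanceConfig()
    rows, records = [], []
    rater_ids = sorted(pathologist_table["rater_id"].unique())
    has_revised = "revised_tps" in pathologist_table.columns
    by_patient = dict(tuple(pathologist_table.groupby("patient_id")))

    for pid, ai in ai_by_patient.items():
        sub = by_patient.get(pid)
        if sub is None:
            continue
        sub = sub.set_index("rater_id").reindex(rater_ids)
        raters = sub["tps"].tolist()
        flags = flag_discrepancies(ai, raters, cfg)
        revised = [None] * len(raters)
        if has_revised:
            revised = [None if pd.isna(v) else float(v) for v in sub["revised_tps"]]
        rec = ConcordanceRecord(
            patient_id=pid, ai_tps=ai, pathologist_tps=raters, flagged=flags,
            cutoff_labels={"ai": ai >= cfg.cutoff_percent,
                           "raters": [v >= cfg.cutoff_percent for v in raters]},
            reassessed=list(flags), revised_tps=revised)
        records.append(rec)
        for rid, rtps, fl in zip(rater_ids, raters, flags):
            rows.append({
                "patient_id": pid, "ai_tps": round(ai, 2), "rater_id": rid,
                "rater_tps": round(rtps, 2), "abs_diff": round(abs(ai - rtps), 2),
                "flagged": fl,
                "ai_cutoff": ai >= cfg.cutoff_percent,
                "rater_cutoff": rtps >= cfg.cutoff_percent,
                "concordant": (ai >= cfg.cutoff_percent) == (rtps >= cfg.cutoff_percent),
            })

    report = pd.DataFrame(rows)
    ai_list = [r.ai_tps for r in records]
    raters_cols = {rid: [r.pathologist_tps[i] for r in records]
                   for i, rid in enumerate(rater_ids)}
    summary = {
        "raters": rater_summary(ai_list, raters_cols, cfg) if len(records) >= 3 else None,
        "reassessment": reassessment_summary(records) if records else None,
        "config": {"delta_pp": cfg.delta_pp, "cutoff_percent": cfg.cutoff_percent,
                   "correlation": cfg.correlation},
    }
    return report, summary, records
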