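"""Cohort statistics over docking-score tables.

A cohort is a table of docked ligands with a group label (pan-kinase inhibitor,
target-specific inhibitor, or test compound), a docking score in kcal/mol
(negative = favorable) and optional per-ligand interaction annotations.  The
analyses mirror the usual virtual-screening triage: per-group mean scores, an
overall-mean affinity cut-off, pass/fail counts per group ("pass" = strictly
more negative than the cut-off), and residue-contact frequency split by group
and by cut-off side.  Also included: the folding-stability label rule for
alanine-scan ΔΔG values and a two-sample t-test for externally computed energy
series (MM/GBSA-style means are consumed, never computed, here).

Interaction annotations use the dialect ``"550:pi_stack;666:hbond"`` — a
semicolon-separated list of ``residue:kind`` items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUPS",
    "CohortSummary",
    "parse_annotations",
    "read_cohort",
    "group_means",
    "overall_cutoff",
    "pass_counts",
    "residue_frequency",
    "stability_label",
    "compare_energy_series",
]

GROUPS = ("pan_tki", "csf1r_specific", "test_compound")

# FoldX-style folding ΔΔG bands, kcal/mol
STABILIZING_RANGE = (-5.0, -0.75)
DESTABILIZING_MIN = 1.0


@dataclass
class CohortSummary:
    group_means: dict[str, float]
    cutoff: float
    pass_counts: dict[str, int]
    group_sizes: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        groups = sorted(self.group_sizes)
        return pd.DataFrame({
            "group": groups,
            "n": [self.group_sizes[g] for g in groups],
            "mean_score": [self.group_means.get(g, np.nan) for g in groups],
            "n_pass": [self.pass_counts.get(g, 0) for g in groups],
        })


def parse_annotations(text) -> list[tuple[int, str]]:
    """Parse the ``residue:kind;residue:kind`` annotation dialect."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    if str(text).strip().lower() in ("", "none", "-"):
        return []
    out = []
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        res, _, kind = item.partition(":")
        out.append((int(res), kind.strip()))
    return out


def read_cohort(source) -> pd.DataFrame:
    """Read a delimited cohort table (ligand, group, score[, interactions])."""
    df = pd.read_csv(source)
    required = {"ligand", "group", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"unknown group label(s) at line(s) {lines}")
    if not np.isfinite(df["score"]).all():
        lines = (df.index[~np.isfinite(df["score"])] + 2).tolist()
        raise ValueError(f"non-finite score(s) at line(s) {lines}")
    return df


def group_means(records: pd.DataFrame) -> dict[str, float]:
    """Arithmetic mean score per group, kcal/mol (report at 4 decimals)."""
    means = {}
    for group, sub in records.groupby("group"):
        if len(sub) == 0:
            raise ValueError(f"group {group!r} is empty")
        means[str(group)] = float(sub["score"].mean())
    return means


def overall_cutoff(records: pd.DataFrame, method="mean_all") -> float:
    """The affinity cut-off: the mean over all records, or an explicit value.

    An explicit number (``method=<float>``) is accepted because a published
    cut-off need not be recomputable from the published table.
    """
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method == "mean_all":
        if len(records) == 0:
            raise ValueError("no records")
        return float(records["score"].mean())
    raise ValueError(f"unknown cut-off method {method!r}")


def pass_counts(records: pd.DataFrame, cutoff: float) -> CohortSummary:
    """Per-group counts of ligands passing the cut-off (score strictly more
    negative than ``cutoff``)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    means = group_means(records)
    passes = {}
    sizes = {}
    for group, sub in records.groupby("group"):
        sizes[str(group)] = int(len(sub))
        passes[str(group)] = int((sub["score"] < cutoff).sum())
    return CohortSummary(group_means=means, cutoff=float(cutoff),
                         pass_counts=passes, group_sizes=sizes)


def residue_frequency(records: pd.DataFrame, residue: int, kinds,
                      cutoff: float) -> pd.DataFrame:
    """Contact-frequency row: ligands having any of ``kinds`` at ``residue``,
    split above/below the cut-off and by group, with a grand total.

    "Above cut-off" means passing (score < cutoff)."""
    if "interactions" not in records.columns:
        raise ValueError("records lack an 'interactions' column")
    missing = records.loc[records["interactions"].isna(), "ligand"].tolist() \
        if records["interactions"].isna().any() else []
    if missing:
        raise ValueError(f"records lacking annotations: {missing}")
    kinds = {kinds} if isinstance(kinds, str) else set(kinds)
    rows = []
    for _, rec in records.iterrows():
        ann = parse_annotations(rec["interactions"])
        hit = any(res == residue and kind in kinds for res, kind in ann)
        rows.append({
            "group": rec["group"],
            "above": bool(hit and rec["score"] < cutoff),
            "below": bool(hit and rec["score"] >= cutoff),
        })
    df = pd.DataFrame(rows)
    out = df.groupby("group")[["above", "below"]].sum().astype(int)
    out.loc["total"] = out.sum()
    out["total"] = out["above"] + out["below"]
    out.attrs["residue"] = residue
    out.attrs["kinds"] = sorted(kinds)
    return out


def stability_label(ddg: float) -> str:
    """Folding ΔΔG label: stabilizing in [−5, −0.75], destabilizing above +1,
    neutral otherwise (kcal/mol)."""
    if not np.isfinite(ddg):
        raise ValueError("ΔΔG must be finite")
    lo, hi = STABILIZING_RANGE
    if lo <= ddg <= hi:
        return "stabilizing"
    if ddg > DESTABILIZING_MIN:
        return "destabilizing"
    return "neutral"


def compare_energy_series(a, b, alpha: float = 0.05,
                          equal_var: bool = True) -> dict:
    """Two-sample t-test on externally computed energy series (e.g. MM/GBSA
    replicate means).  Returns the difference of means, the two-sided p-value
    and a significance flag at ``alpha``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each series needs at least 2 samples")
    diff = float(b.mean() - a.mean())
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and np.isclose(a.mean(), b.mean()):
        return {"difference": 0.0, "p_value": 1.0, "significant": False}
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return {"difference": diff, "p_value": float(p), "significant": bool(p < alpha)}
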