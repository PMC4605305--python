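"""PSI quantification: coverage filtering, per-replicate PSI, condition
means, delta-PSI and the replicate-level significance test.

PSI (percent spliced in) is the percentage of an event's reads that
support the longest (exon-inclusion) isoform:
``100 * long / (long + short)``, undefined at zero total coverage.
Condition means average the defined replicate values; delta-PSI is the
difference of condition means with a fixed first-minus-second sign
convention. Events are pre-filtered for a minimum mean total read count
(default 10) across all samples.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import PsiTable, SampleSpec, condition_of


def filter_low_coverage(counts: pd.DataFrame, min_mean_reads: float = 10.0) -> pd.DataFrame:
    """Keep events whose mean total count over all samples is >= the
    threshold (inclusive)."""
    if min_mean_reads < 0:
        raise ValueError("min_mean_reads must be >= 0")
    totals = counts["long_count"] + counts["short_count"]
    mean_by_event = totals.groupby(counts["event_id"]).mean()
    keep = set(mean_by_event.index[mean_by_event >= min_mean_reads])
    return counts[counts["event_id"].isin(keep)].reset_index(drop=True)


def compute_psi(counts: pd.DataFrame, samples: Sequence[SampleSpec] | None = None) -> PsiTable:
    """Compute per-replicate PSI and condition means from a count table.

    The condition of each sample is taken from ``samples`` when given,
    otherwise parsed from the sample id (``<condition>_rep<k>``). Replicates
    with zero total coverage have undefined (NaN) PSI and are excluded from
    condition means rather than imputed.
    """
    reps = counts.copy()
    if samples is not None:
        cond_map = {s.sample_id: s.condition for s in samples}
        reps["condition"] = reps["sample_id"].map(cond_map)
        if reps["condition"].isna().any():
            missing = reps.loc[reps["condition"].isna(), "sample_id"].unique()
            raise ValueError(f"samples sheet lacks entries for {list(missing)[:5]}")
    else:
        reps["condition"] = reps["sample_id"].map(condition_of)
    reps["total_count"] = reps["long_count"] + reps["short_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        reps["psi"] = np.where(
            reps["total_count"] > 0,
            100.0 * reps["long_count"] / reps["total_count"],
            np.nan,
        )
    means = (
        reps.groupby(["event_id", "condition"], sort=True)["psi"]
        .agg(mean_psi="mean", n_replicates_used="count")
        .reset_index()
    )
    means["n_replicates_used"] = means["n_replicates_used"].astype(int)
    return PsiTable(replicates=reps, condition_means=means)


def test_psi_difference(
    psi_reps_a: Sequence[float], psi_reps_b: Sequence[float]
) -> float:
    """Two-sided Welch (unequal-variance) t-test on replicate PSI values.

    Returns NaN when either group has fewer than two defined values
    (untestable event). Zero-variance corner cases are resolved by limits:
    identical constant groups give p = 1, distinct constant groups p = 0.
    """
    a = np.asarray(psi_reps_a, dtype=float)
    b = np.asarray(psi_reps_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    with warnings.catch_warnings():
        # near-constant replicate groups trip scipy's precision-loss warning
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def delta_psi(
    psi: PsiTable,
    condition_a: str,
    condition_b: str,
    with_test: bool = True,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Delta-PSI records between two conditions, with optional Welch test.

    delta_psi = mean_psi(condition_a) - mean_psi(condition_b). Events with
    no defined replicate in a condition get NaN delta; events with fewer
    than two defined replicates on either side get NaN p-value and
    ``testable = False``. ``adjust='bh'`` appends Benjamini-Hochberg
    adjusted p-values (raw p-values are the default decision variable).
    """
    present = set(psi.condition_means["condition"])
    for cond in (condition_a, condition_b):
        if cond not in present:
            raise ValueError(f"condition {cond!r} absent from PSI table")
    wide = psi.means_wide()
    out = pd.DataFrame(
        {
            "event_id": wide.index,
            "condition_a": condition_a,
            "condition_b": condition_b,
            "delta_psi": (wide[condition_a] - wide[condition_b]).to_numpy(),
        }
    )
    if with_test:
        reps = psi.replicates
        grouped = {
            (eid, cond): grp["psi"].to_numpy()
            for (eid, cond), grp in reps.groupby(["event_id", "condition"], sort=False)
        }
        pvals = []
        for eid in wide.index:
            pa = grouped.get((eid, condition_a), np.array([]))
            pb = grouped.get((eid, condition_b), np.array([]))
            pvals.append(test_psi_difference(pa, pb))
        out["p_value"] = pvals
    else:
        out["p_value"] = np.nan
    out["testable"] = ~out["p_value"].isna()
    if adjust is not None:
        if adjust != "bh":
            raise ValueError("adjust must be None or 'bh'")
        mask = out["testable"].to_numpy()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask] = stats.false_discovery_control(out.loc[mask, "p_value"], method="bh")
        out["p_adjusted"] = adj
    return out
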