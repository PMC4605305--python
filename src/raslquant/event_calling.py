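"""PSF-dependence calling, exon direction labels, and TRAP150-antagonism
classification.

Two published call criteria are implemented as named, composable filters:

* the *methods* criterion — |PSI_WT-S − PSI_PSF-KD-S| >= 10 (inclusive)
  with p < 0.05;
* the *results* criterion — a stimulation response |PSI_WT-S − PSI_WT-U|
  strictly > 9, plus a rescue fraction
  (PSI_WT-S − PSI_PSF-KD-S) / (PSI_WT-S − PSI_WT-U) >= 0.6 with both
  differences of the same sign, plus p < 0.05.

The rescue fraction measures how much of the stimulation-induced PSI
change is reverted by PSF knockdown; the sign-aware reading is required so
that PSF-repressed exons (negative differences) are scored symmetrically.
When only condition means are available (as in the packaged reference
table) the p-value term is dropped in declared *magnitude-only* mode.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

WT_U = "WT_U"
WT_S = "WT_S"
PSF_KD_S = "PSF_KD_S"
TRAP150_KD_U = "TRAP150_KD_U"

DIRECTION_ENHANCED = "PSF_enhanced"
DIRECTION_REPRESSED = "PSF_repressed"
DIRECTION_INDETERMINATE = "indeterminate"

LABEL_ANTAGONISTIC = "antagonistic"
LABEL_SAME_DIRECTION = "same_direction"
LABEL_INDETERMINATE = "indeterminate"


def rescue_fraction(psi_wt_u, psi_wt_s, psi_kd_s):
    """Fraction of the stimulation-induced PSI change reverted by PSF
    knockdown: (PSI_WT-S − PSI_PSF-KD-S) / (PSI_WT-S − PSI_WT-U).

    NaN when the stimulation response is zero (undefined). Positive values
    mean knockdown moved PSI back toward the unstimulated level; 1.0 is
    full reversion. Invariant under flipping the inclusion orientation
    (PSI -> 100 − PSI). Accepts scalars or array-likes.
    """
    num = np.asarray(psi_wt_s, dtype=float) - np.asarray(psi_kd_s, dtype=float)
    den = np.asarray(psi_wt_s, dtype=float) - np.asarray(psi_wt_u, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    if frac.ndim == 0:
        return float(frac)
    return frac


def _check_conditions(means: pd.DataFrame, required: tuple[str, ...]) -> None:
    missing = [c for c in required if c not in means.columns]
    if missing:
        raise ValueError(f"condition means missing column(s): {missing}")


def _pval_series(
    means: pd.DataFrame, pvals: Mapping[str, float] | pd.Series | None
) -> pd.Series:
    if pvals is None:
        return pd.Series(np.nan, index=means.index)
    return pd.Series(pvals).reindex(means.index)


def _base_calls(
    means: pd.DataFrame, pvals: Mapping[str, float] | pd.Series | None
) -> pd.DataFrame:
    calls = pd.DataFrame(index=means.index)
    calls["gene_symbol"] = (
        means["gene_symbol"] if "gene_symbol" in means.columns else means.index
    )
    calls["delta_psi_kd"] = means[WT_S] - means[PSF_KD_S]
    if WT_U in means.columns:
        calls["delta_psi_stim_response"] = means[WT_S] - means[WT_U]
        calls["rescue_fraction"] = rescue_fraction(
            means[WT_U], means[WT_S], means[PSF_KD_S]
        )
    else:
        calls["delta_psi_stim_response"] = np.nan
        calls["rescue_fraction"] = np.nan
    calls["p_value"] = _pval_series(means, pvals)
    return calls


def call_psf_dependent_methods(
    means: pd.DataFrame,
    pvals: Mapping[str, float] | pd.Series | None = None,
    delta_threshold: float = 10.0,
    alpha: float = 0.05,
    magnitude_only: bool = False,
) -> pd.DataFrame:
    """Apply the methods-form criterion: |WT_S − PSF_KD_S| >= threshold
    (inclusive) and p < alpha.

    ``means`` is an event x condition DataFrame (index event_id) with at
    least WT_S and PSF_KD_S columns. In magnitude-only mode the p-value
    clause is skipped and the output is flagged accordingly.
    """
    _check_conditions(means, (WT_S, PSF_KD_S))
    if pvals is None and not magnitude_only:
        raise ValueError(
            "p-values required unless magnitude_only=True is declared"
        )
    calls = _base_calls(means, pvals)
    magnitude_ok = calls["delta_psi_kd"].abs() >= delta_threshold
    if magnitude_only:
        calls["passes_methods_criterion"] = magnitude_ok
    else:
        calls["passes_methods_criterion"] = magnitude_ok & (calls["p_value"] < alpha)
    calls["magnitude_only"] = magnitude_only
    return classify_direction(calls.reset_index(names="event_id"))


def call_psf_dependent_results(
    means: pd.DataFrame,
    pvals: Mapping[str, float] | pd.Series | None = None,
    stim_threshold: float = 9.0,
    rescue_threshold: float = 0.6,
    alpha: float = 0.05,
    magnitude_only: bool = False,
) -> pd.DataFrame:
    """Apply the results-form criterion: stimulation response strictly
    above ``stim_threshold``, sign-aware rescue fraction >=
    ``rescue_threshold`` (inclusive), and p < alpha unless magnitude-only.

    Events with zero stimulation response have an undefined rescue
    fraction and are excluded from the call with ``rescue_defined=False``.
    """
    _check_conditions(means, (WT_U, WT_S, PSF_KD_S))
    if pvals is None and not magnitude_only:
        raise ValueError(
            "p-values required unless magnitude_only=True is declared"
        )
    calls = _base_calls(means, pvals)
    stim_ok = calls["delta_psi_stim_response"].abs() > stim_threshold
    frac = calls["rescue_fraction"]
    calls["rescue_defined"] = ~frac.isna()
    # frac >= threshold > 0 already forces both differences to share a sign
    rescue_ok = calls["rescue_defined"] & (frac >= rescue_threshold)
    passes = stim_ok & rescue_ok
    if not magnitude_only:
        passes = passes & (calls["p_value"] < alpha)
    calls["passes_results_criterion"] = passes
    calls["magnitude_only"] = magnitude_only
    return classify_direction(calls.reset_index(names="event_id"))


def classify_direction(calls: pd.DataFrame) -> pd.DataFrame:
    """Label each event PSF_enhanced (knockdown lowers inclusion, so PSF
    promotes it), PSF_repressed, or indeterminate at exactly zero."""
    d = calls["delta_psi_kd"]
    calls = calls.copy()
    calls["direction"] = np.select(
        [d > 0, d < 0],
        [DIRECTION_ENHANCED, DIRECTION_REPRESSED],
        default=DIRECTION_INDETERMINATE,
    )
    return calls


def call_trap150_antagonism(
    psi_wt_u: float,
    psi_trapkd_u: float,
    psi_wt_s: float,
    psi_psfkd_s: float,
    margin: float = 5.0,
) -> dict:
    """Classify one event's TRAP150 regulation relative to stimulation.

    TRAP150 sequesters PSF in resting cells, so depleting TRAP150 without
    stimulation should move a PSF-target exon's inclusion in the same
    direction as stimulation does (*antagonistic* regulation of PSF by
    TRAP150). The call compares the sign of the TRAP150-KD shift
    (TRAP150_KD_U − WT_U) with the stimulation shift (WT_S − WT_U);
    shifts smaller than ``margin`` (default 5 pp, the assay's replicate
    standard deviation) are *indeterminate*.
    """
    stim_shift = psi_wt_s - psi_wt_u
    trap_kd_shift = psi_trapkd_u - psi_wt_u
    if abs(trap_kd_shift) < margin:
        label = LABEL_INDETERMINATE
    elif np.sign(trap_kd_shift) == np.sign(stim_shift):
        label = LABEL_ANTAGONISTIC
    else:
        label = LABEL_SAME_DIRECTION
    return {
        "psf_direction": float(np.sign(psi_wt_s - psi_psfkd_s)),
        "trap_kd_shift": float(trap_kd_shift),
        "stim_shift": float(stim_shift),
        "label": label,
    }


def classify_antagonism(means: pd.DataFrame, margin: float = 5.0) -> pd.DataFrame:
    """Per-event TRAP150-antagonism calls for a condition-mean table with
    WT_U, WT_S, PSF_KD_S and TRAP150_KD_U columns."""
    _check_conditions(means, (WT_U, WT_S, PSF_KD_S, TRAP150_KD_U))
    rows = []
    for eid, row in means.iterrows():
        call = call_trap150_antagonism(
            row[WT_U], row[TRAP150_KD_U], row[WT_S], row[PSF_KD_S], margin=margin
        )
        call["event_id"] = eid
        rows.append(call)
    out = pd.DataFrame(
        rows, columns=["event_id", "psf_direction", "trap_kd_shift", "stim_shift", "label"]
    )
    return out
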