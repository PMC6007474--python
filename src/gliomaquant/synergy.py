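"""Projected-additive (Bliss-style) two-agent synergy classification.

Raw plate-reader values are normalised to the untreated-control mean so that
the control reads 1.0 ("100% metabolic activity").  For a combination of
agents A and B, the projected additive effect under independence is the
product of the single-agent surviving fractions, f_A·f_B.  The observed
combination replicates are compared with a replicate-level projected sample;
a combination whose observed metabolic activity is statistically lower than
projected is called synergistic, statistically higher antagonistic, and a
non-significant contrast additive.

Two ways of forming the replicate-level projected sample are provided:

* ``matched`` (default): element-wise products of same-index monotherapy
  replicates, giving n independent projected values.  This keeps the
  observed-vs-projected test calibrated — its false non-additive rate under
  a true Bliss-independent combination matches the nominal α.
* ``pairwise``: all n_a·n_b cross products.  These share factors and are
  therefore correlated; treating them as independent replicates inflates the
  false non-additive rate well above α, so this mode is provided only for
  comparison with analyses that used it.

When several dose levels are tested jointly, Tukey's HSD across the pooled
set of observed/projected groups controls the family-wise error rate;
an unadjusted per-dose mode is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "SynergyCall",
    "normalize_viability",
    "projected_additive",
    "classify_interaction",
    "synergy_report",
    "report_to_frame",
]

_LABELS = ("synergistic", "additive", "antagonistic")


@dataclass
class SynergyCall:
    """Classification of one observed-vs-projected contrast."""

    dose_label: str
    projected_sample: np.ndarray
    observed_sample: np.ndarray
    p_value: float
    classification: str
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def projected_mean(self) -> float:
        return float(np.mean(self.projected_sample))

    @property
    def observed_mean(self) -> float:
        return float(np.mean(self.observed_sample))


def normalize_viability(table: pd.DataFrame, control_group: str = "control",
                        group_col: str = "group",
                        value_col: str | None = None) -> pd.DataFrame:
    """Divide every value by the control-group mean.

    The control mean maps to exactly 1.0, so normalising an already
    normalised table is a no-op.  The value column is auto-detected as
    ``fraction`` or ``value`` when not named explicitly.
    """
    if value_col is None:
        for cand in ("fraction", "value"):
            if cand in table.columns:
                value_col = cand
                break
        else:
            raise ValueError("no 'fraction' or 'value' column found")
    ctrl = table.loc[table[group_col] == control_group, value_col]
    if len(ctrl) < 2:
        raise ValueError("control group needs at least 2 replicates")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean <= 0:
        raise ValueError(f"control mean must be > 0, got {ctrl_mean}")
    out = table.copy()
    out["fraction"] = out[value_col] / ctrl_mean
    if value_col != "fraction":
        out = out.drop(columns=[value_col])
    return out


def projected_additive(fa, fb, pairing: str = "pairwise") -> np.ndarray:
    """Replicate-level projected-additive (independence) sample.

    Parameters
    ----------
    fa, fb : array-like
        Surviving fractions under each agent alone.
    pairing : {"pairwise", "matched"}
        ``pairwise`` returns all cross products fa_i·fb_j; ``matched``
        returns element-wise products of same-index replicates (requires
        equal lengths) and is what the classification pipeline uses.
    """
    fa = np.asarray(fa, dtype=np.float64)
    fb = np.asarray(fb, dtype=np.float64)
    if fa.size == 0 or fb.size == 0:
        raise ValueError("both monotherapy samples must be non-empty")
    if (fa < 0).any() or (fb < 0).any():
        raise ValueError("surviving fractions must be >= 0")
    if pairing == "pairwise":
        return np.outer(fa, fb).ravel()
    if pairing == "matched":
        if fa.size != fb.size:
            raise ValueError("matched pairing requires equal replicate counts; "
                             "use pairing='pairwise' for unequal samples")
        return fa * fb
    raise ValueError(f"unknown pairing {pairing!r}")


def _direction(observed_mean: float, projected_mean: float) -> str:
    if observed_mean < projected_mean:
        return "synergistic"
    return "antagonistic"


def classify_interaction(observed, projected, alpha: float = 0.05,
                         dose_label: str = "") -> SynergyCall:
    """Two-group observed-vs-projected comparison with a three-way call.

    Uses the Welch two-sample t statistic: the projected sample is a
    product of two replicate samples and so carries roughly twice the
    relative variance of the observed sample, which the pooled (equal
    variance) form would understate.  Identical zero-variance samples are
    flagged degenerate and called additive with p = 1.
    """
    obs = np.asarray(observed, dtype=np.float64)
    proj = np.asarray(projected, dtype=np.float64)
    if obs.size < 2 or proj.size < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled_var = np.var(obs, ddof=1) + np.var(proj, ddof=1)
    if pooled_var == 0.0:
        if np.isclose(obs.mean(), proj.mean()):
            return SynergyCall(dose_label, proj, obs, 1.0, "additive",
                               alpha, degenerate=True)
        return SynergyCall(dose_label, proj, obs, 0.0,
                           _direction(obs.mean(), proj.mean()),
                           alpha, degenerate=True)
    _, p = stats.ttest_ind(obs, proj, equal_var=False)
    p = float(p)
    label = _direction(obs.mean(), proj.mean()) if p < alpha else "additive"
    return SynergyCall(dose_label, proj, obs, p, label, alpha)


def synergy_report(table: pd.DataFrame, dose_levels: list[str],
                   alpha: float = 0.05, pairing: str = "matched",
                   multiplicity: str = "joint",
                   a_group: str = "A",
                   b_group_fmt: str = "B:{dose}",
                   ab_group_fmt: str = "AB:{dose}",
                   group_col: str = "group") -> list[SynergyCall]:
    """One synergy call per dose level from a long-format fraction table.

    The table must already be in fraction units (see
    :func:`normalize_viability`) and carry an ``a_group`` monotherapy group
    plus, per dose, the B monotherapy and AB combination groups.  Dose
    levels with a missing group are skipped with a warning.

    ``multiplicity='joint'`` runs Tukey's HSD over the pooled set of
    observed and projected groups (family-wise control across doses);
    ``'per_dose'`` classifies each dose independently at ``alpha``.
    """
    if multiplicity not in ("joint", "per_dose"):
        raise ValueError(f"unknown multiplicity {multiplicity!r}")
    value_col = "fraction" if "fraction" in table.columns else "value"
    fa = table.loc[table[group_col] == a_group, value_col].to_numpy()
    if fa.size == 0:
        raise ValueError(f"missing monotherapy group {a_group!r}")

    samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for dose in dose_levels:
        b_name = b_group_fmt.format(dose=dose)
        ab_name = ab_group_fmt.format(dose=dose)
        fb = table.loc[table[group_col] == b_name, value_col].to_numpy()
        obs = table.loc[table[group_col] == ab_name, value_col].to_numpy()
        if fb.size < 2 or obs.size < 2:
            warnings.warn(f"dose level {dose!r}: missing group "
                          f"{b_name if fb.size < 2 else ab_name!r}; skipped",
                          stacklevel=2)
            continue
        samples[dose] = (projected_additive(fa, fb, pairing=pairing), obs)

    if not samples:
        return []
    if multiplicity == "per_dose" or len(samples) == 1:
        return [classify_interaction(obs, proj, alpha=alpha, dose_label=d)
                for d, (proj, obs) in samples.items()]

    values, labels = [], []
    for dose, (proj, obs) in samples.items():
        values.extend(proj)
        labels.extend([f"proj::{dose}"] * len(proj))
        values.extend(obs)
        labels.extend([f"obs::{dose}"] * len(obs))
    values = np.asarray(values)
    if np.var(values) == 0.0:
        # Tukey is undefined without within-group variance; fall back to the
        # degenerate per-dose rule.
        return [classify_interaction(obs, proj, alpha=alpha, dose_label=d)
                for d, (proj, obs) in samples.items()]
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pair_p = {frozenset(pair): float(p) for pair, p in
              zip(combinations(res.groupsunique, 2), res.pvalues)}
    calls = []
    for dose, (proj, obs) in samples.items():
        p = pair_p[frozenset((f"proj::{dose}", f"obs::{dose}"))]
        label = (_direction(obs.mean(), proj.mean())
                 if p < alpha else "additive")
        calls.append(SynergyCall(dose, proj, obs, p, label, alpha))
    return calls


def report_to_frame(calls: list[SynergyCall]) -> pd.DataFrame:
    """Tidy per-dose summary table of a synergy report."""
    return pd.DataFrame([
        {"dose": c.dose_label,
         "projected_mean": c.projected_mean,
         "observed_mean": c.observed_mean,
         "p_value": c.p_value,
         "classification": c.classification}
        for c in calls
    ])
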