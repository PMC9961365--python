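"""Simple inferential statistics and the mixed-ANOVA delegation contract.

The package computes one-sample t-tests and descriptives directly; the
2 x 3 (and larger) mixed-design ANOVAs are delegated to an established
repeated-measures routine behind a fixed interface. Bayesian model
averaging (Bayes-factor analyses) is out of scope: the result schema
reserves optional fields so externally computed values can be merged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Raised when a test needs more observations than supplied."""


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    sd: float
    n: int

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p,
                "mean": self.mean, "sd": self.sd, "n": self.n}


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Classical one-sample t-test against ``mu0`` (two-sided).

    t = (mean - mu0) * sqrt(n) / sd with n-1 degrees of freedom. A
    zero-variance sample returns t = 0 when the mean equals ``mu0`` and an
    infinite statistic (p = 0) otherwise.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise InsufficientDataError("one_sample_t needs a 1-d sample with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = len(x)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == mu0:
            return TTestResult(0.0, df, 1.0, mean, sd, n)
        t = math.inf if mean > mu0 else -math.inf
        return TTestResult(t, df, 0.0, mean, sd, n)
    t = (mean - mu0) * math.sqrt(n) / sd
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p), mean, sd, n)


def group_descriptives(scores_by_group: dict[str, "np.ndarray | list"]) -> pd.DataFrame:
    """Per-group n, mean, SD, median and SEM; empty groups are omitted."""
    rows = []
    for group in scores_by_group:
        x = np.asarray(scores_by_group[group], dtype=float)
        x = x[np.isfinite(x)]
        if len(x) == 0:
            logger.warning("group %s is empty; omitted from descriptives", group)
            continue
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else np.nan
        rows.append(
            {
                "group": group,
                "n": len(x),
                "mean": float(np.mean(x)),
                "sd": sd,
                "median": float(np.median(x)),
                "sem": sd / math.sqrt(len(x)) if len(x) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


class DegenerateVarianceError(ValueError):
    """Raised when all within-cell variance vanishes and F is undefined."""


def mixed_anova_contract(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str = "participant_id",
) -> pd.DataFrame:
    """Mixed-design ANOVA: one within factor, one between factor.

    The computation is delegated to ``pingouin.mixed_anova``; this contract
    fixes only the interface and output schema. Returns a tidy effects
    table with columns ``effect``, ``F``, ``df1``, ``df2``, ``p``, ``np2``
    (partial eta squared), plus sphericity metadata where applicable and
    reserved (empty) Bayes-factor columns. The design must be balanced:
    every subject contributes exactly one value per within level.

    Degenerate input (zero variance within every cell but differing cell
    means) raises :class:`DegenerateVarianceError` instead of emitting
    numbers; a globally constant dv returns F = 0 for every effect.
    """
    cells = data.groupby([subject, within], observed=True)[dv].count()
    if (cells != 1).any():
        bad = cells[cells != 1]
        raise ValueError(
            "unbalanced design; offending (subject, within) cells: "
            f"{list(bad.index[:10])}"
        )
    per_level = data.groupby(within, observed=True)[subject].nunique()
    if per_level.nunique() != 1:
        raise ValueError(f"unbalanced design across within levels: {dict(per_level)}")

    values = data[dv].to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        effects = [within, between, "Interaction"]
        return pd.DataFrame(
            {
                "effect": effects,
                "F": 0.0,
                "df1": np.nan,
                "df2": np.nan,
                "p": 1.0,
                "np2": 0.0,
                "sphericity_corrected": False,
                "BF_incl": np.nan,
                "BF_excl": np.nan,
            }
        )
    cell_var = data.groupby([between, within], observed=True)[dv].var(ddof=1)
    if np.allclose(cell_var.fillna(0.0), 0.0):
        raise DegenerateVarianceError(
            "all within-cell variances are zero while cell means differ; "
            "F statistics are undefined for this input"
        )

    import pingouin as pg

    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject,
        correction="auto",
    )
    aov.columns = [c.replace("-", "_") for c in aov.columns]
    sphericity_known = "sphericity" in aov.columns
    rows = []
    for _, r in aov.iterrows():
        corrected = False
        p = r["p_unc"]
        gg = r.get("p_GG_corr", np.nan)
        if sphericity_known and r.get("sphericity") is False and np.isfinite(gg):
            p = gg
            corrected = True
        rows.append(
            {
                "effect": r["Source"],
                "F": float(r["F"]),
                "df1": float(r["DF1"]),
                "df2": float(r["DF2"]),
                "p": float(p),
                "np2": float(r["np2"]),
                "sphericity_corrected": corrected,
                "BF_incl": np.nan,
                "BF_excl": np.nan,
            }
        )
    if not sphericity_known:
        logger.warning("sphericity test unavailable; uncorrected df reported")
    return pd.DataFrame(rows)


def bonferroni(p_values, n_comparisons: int | None = None) -> np.ndarray:
    """Bonferroni correction: multiply p by the comparison count, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    m = n_comparisons if n_comparisons is not None else len(p)
    return np.minimum(p * m, 1.0)
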