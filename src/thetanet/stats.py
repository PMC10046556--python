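"""Repeated-measures statistics for the condition-wise network metrics.

The design is fully within-subject: every subject contributes one value
per (test, scenario) cell (trials averaged first).  ``rm_anova_2way``
partitions the sums of squares into the two main effects, their
interaction, the subject stratum and the three subject-by-effect error
strata, forms the usual F ratios, and applies the Greenhouse–Geisser
sphericity correction *unconditionally* — conservative, and free of an
arbitrary Mauchly threshold.  Effect sizes are generalized eta squared,

    eta_g^2 = SS_effect / (SS_effect + SS_subjects + sum of error SS),

the formulation appropriate for fully within designs and comparable
across study types.  Post hoc comparisons are paired t-tests with
Bonferroni correction; mass-univariate helpers repeat the ANOVA over
channels or channel pairs with the Bonferroni divisor equal to the
number of units tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)

_TINY = 1e-12


@dataclass
class AnovaResult:
    """One effect of a two-way within-subject ANOVA (G-G corrected)."""

    effect: str
    F: float
    df1: float  # G-G corrected numerator df
    df2: float  # G-G corrected denominator df
    epsilon: float
    p: float
    eta_g2: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "effect": self.effect, "F": self.F, "df1": self.df1,
            "df2": self.df2, "epsilon": self.epsilon, "p": self.p,
            "eta_g2": self.eta_g2, "degenerate": self.degenerate,
        }


def results_to_frame(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def _cell_array(
    data: pd.DataFrame, dv: str, subject: str, a: str, b: str
) -> tuple[np.ndarray, list, list, list]:
    """Subjects x A x B cell-mean array; errors on missing cells."""
    cells = data.groupby([subject, a, b], sort=True)[dv].mean()
    subjects = sorted(data[subject].unique())
    a_levels = sorted(data[a].unique())
    b_levels = sorted(data[b].unique())
    missing = [
        (s, ai, bi)
        for s in subjects
        for ai in a_levels
        for bi in b_levels
        if (s, ai, bi) not in cells.index
    ]
    if missing:
        raise ValueError(f"incomplete within-subject design; missing cells: {missing}")
    y = np.array(
        [[[cells[(s, ai, bi)] for bi in b_levels] for ai in a_levels]
         for s in subjects]
    )
    return y, subjects, a_levels, b_levels


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast rows (orthogonal complement of 1)."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis.T)
    return q[:, : k - 1].T


def _gg_epsilon(t: np.ndarray, k_eff: int) -> float:
    """Greenhouse–Geisser epsilon from contrast-transformed scores.

    ``t`` is subjects x (k_eff) transformed data; epsilon is
    tr(M)^2 / (k_eff * tr(M^2)) for M the covariance of the transformed
    scores, bounded to [1/k_eff, 1].
    """
    if k_eff <= 1:
        return 1.0
    m = np.cov(t, rowvar=False, ddof=1)
    tr = np.trace(m)
    tr2 = np.trace(m @ m)
    if tr2 <= _TINY:
        return 1.0
    eps = tr**2 / (k_eff * tr2)
    return float(np.clip(eps, 1.0 / k_eff, 1.0))


def rm_anova_2way(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: tuple[str, str] = ("test", "scenario"),
    return_ss: bool = False,
) -> list[AnovaResult] | tuple[list[AnovaResult], dict[str, float]]:
    """Two-way fully-within-subject ANOVA with unconditional G-G correction.

    Requires a complete crossed design (every subject has every A x B
    cell; replicate rows are cell-averaged first) and at least 3
    subjects.  Returns results for effect A, effect B and A x B; effects
    whose factor has a single level are omitted, so the call degrades
    gracefully to a one-way repeated-measures ANOVA.

    A zero-variance error stratum is flagged ``degenerate``: F is 0 when
    the effect is also null, infinite otherwise.  With ``return_ss`` the
    full sums-of-squares partition is returned alongside the results.
    """
    a_name, b_name = within
    y, subjects, a_levels, b_levels = _cell_array(data, dv, subject, a_name, b_name)
    n, a, b = y.shape
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_sab = np.sum(resid**2)

    ss_err_total = ss_sa + ss_sb + ss_sab

    c_a = _orthonormal_contrasts(a)
    c_b = _orthonormal_contrasts(b)
    eps_a = _gg_epsilon(y.mean(axis=2) @ c_a.T, a - 1)
    eps_b = _gg_epsilon(y.mean(axis=1) @ c_b.T, b - 1)
    t_ab = y.reshape(n, a * b) @ np.kron(c_a, c_b).T
    eps_ab = _gg_epsilon(t_ab, (a - 1) * (b - 1))

    specs = [
        (a_name, ss_a, a - 1, ss_sa, (a - 1) * (n - 1), eps_a),
        (b_name, ss_b, b - 1, ss_sb, (b - 1) * (n - 1), eps_b),
        (f"{a_name}:{b_name}", ss_ab, (a - 1) * (b - 1), ss_sab,
         (a - 1) * (b - 1) * (n - 1), eps_ab),
    ]
    specs = [s for s in specs if s[2] > 0]  # drop single-level factors
    results = []
    for name, ss_eff, df1, ss_err, df2, eps in specs:
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        degenerate = ms_err <= _TINY
        if degenerate:
            if ms_eff <= _TINY:
                f_stat, p = 0.0, 1.0
            else:
                f_stat, p = np.inf, 0.0
            logger.warning("rm_anova_2way: zero error variance for effect %s", name)
        else:
            f_stat = ms_eff / ms_err
            p = float(sstats.f.sf(f_stat, df1 * eps, df2 * eps))
        eta = ss_eff / (ss_eff + ss_s + ss_err_total) if ss_eff > 0 else 0.0
        results.append(
            AnovaResult(
                effect=name, F=float(f_stat), df1=df1 * eps, df2=df2 * eps,
                epsilon=eps, p=float(p), eta_g2=float(eta), degenerate=degenerate,
            )
        )
    if return_ss:
        ss = {
            "subjects": float(ss_s), a_name: float(ss_a), b_name: float(ss_b),
            f"{a_name}:{b_name}": float(ss_ab),
            f"subjects:{a_name}": float(ss_sa),
            f"subjects:{b_name}": float(ss_sb),
            f"subjects:{a_name}:{b_name}": float(ss_sab),
        }
        return results, ss
    return results


def condition_average(
    data: pd.DataFrame,
    dv: str = "value",
    keys: tuple[str, ...] = ("subject", "test", "scenario"),
) -> pd.DataFrame:
    """Collapse trial-level rows to cell means per (subject, test, scenario)."""
    if data.empty:
        raise ValueError("empty table")
    out = data.groupby(list(keys), sort=True, as_index=False)[dv].mean()
    return out


def posthoc_paired(
    data: pd.DataFrame,
    comparisons: list[tuple[tuple, tuple]],
    family_size: int | None = None,
    dv: str = "value",
    subject: str = "subject",
    cell_keys: tuple[str, str] = ("test", "scenario"),
) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests between design cells.

    Each comparison is a pair of (test, scenario) cells; values are
    matched within subject.  ``family_size`` defaults to the number of
    comparisons.  Zero-variance differences are flagged degenerate
    rather than yielding an infinite t.
    """
    if family_size is None:
        family_size = len(comparisons)
    cells = data.groupby([subject, *cell_keys], sort=True)[dv].mean()
    rows = []
    for cell_x, cell_y in comparisons:
        x = cells.xs(cell_x, level=cell_keys).sort_index()
        y = cells.xs(cell_y, level=cell_keys).sort_index()
        if not x.index.equals(y.index):
            raise ValueError(f"cells {cell_x} vs {cell_y}: unmatched subjects")
        if len(x) < 3:
            raise ValueError("need >= 3 paired differences")
        diff = x.to_numpy() - y.to_numpy()
        degenerate = diff.std(ddof=1) <= _TINY
        if degenerate:
            if abs(diff.mean()) <= _TINY:
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = np.nan, np.nan
        else:
            t_stat, p = sstats.ttest_rel(x, y)
        rows.append({
            "cell_x": cell_x, "cell_y": cell_y, "t": float(t_stat),
            "df": len(x) - 1, "p_raw": float(p),
            "p_corrected": float(min(1.0, p * family_size)) if np.isfinite(p) else np.nan,
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def mass_univariate(
    data: pd.DataFrame,
    unit: str = "unit",
    alpha: float = 0.05,
    dv: str = "value",
    subject: str = "subject",
    within: tuple[str, str] = ("test", "scenario"),
) -> pd.DataFrame:
    """Repeat the two-way RM-ANOVA per unit (channel or channel pair).

    The significance flag uses the Bonferroni divisor equal to the
    number of units: an effect is flagged when p < alpha / n_units.
    Units with degenerate (zero-variance) strata are skipped with a
    logged reason.
    """
    units = sorted(data[unit].unique())
    n_units = len(units)
    rows = []
    for u in units:
        sub = data[data[unit] == u]
        try:
            results = rm_anova_2way(sub, dv=dv, subject=subject, within=within)
        except ValueError as exc:
            logger.warning("mass_univariate: unit %s skipped (%s)", u, exc)
            continue
        if any(r.degenerate for r in results):
            logger.warning("mass_univariate: unit %s degenerate; skipped", u)
            continue
        for r in results:
            d = r.to_dict()
            d[unit] = u
            d["significant"] = r.p < alpha / n_units
            rows.append(d)
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_divisor"] = n_units
    return out


def bonferroni_divisor_for_pairs(channel_labels) -> int:
    """Number of unique channel pairs — the pair-level Bonferroni divisor."""
    n = len(channel_labels)
    return n * (n - 1) // 2
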