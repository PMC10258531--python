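"""Group statistics: Welch t-tests, split-plot (mixed) ANOVA/ANCOVA with
sphericity handling, and FDR-corrected post-hoc comparisons.

The mixed ANOVA is the classical univariate split-plot decomposition.
Between-participant effects are tested against the participant error stratum
(OLS on participant means with sum-to-zero contrasts and Type III sums of
squares, so unbalanced cells are handled marginally). Within-participant
effects are tested in the participant-by-within stratum via orthonormal
contrasts of the within levels. For within factors with three or more levels
Mauchly's W is computed and the Huynh-Feldt epsilon is applied to the within
degrees of freedom whenever sphericity is rejected at alpha = 0.05; epsilon
is reported regardless. Covariates enter additively in the between stratum
only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg
from scipy import stats as sps

from .errors import (
    CollinearityError,
    DegenerateTestError,
    InvalidParameterError,
    SingularMatrixError,
    UnbalancedDesignError,
)

SPHERICITY_ALPHA = 0.05
_COND_LIMIT = 1e8


# --------------------------------------------------------------------------
# t tests
# --------------------------------------------------------------------------


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    direction: str


def welch_t(a, b, labels: Tuple[str, str] = ("a", "b")) -> TTestResult:
    """Two-sided Welch t-test of ``mean(a) - mean(b)``.

    Sample SDs use the n-1 denominator; degrees of freedom follow
    Welch-Satterthwaite. ``direction`` records the subtraction order.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateTestError("both samples have zero variance")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(
        t=float(t),
        df=float(df),
        p=float(p),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(np.sqrt(va)),
        sd_b=float(np.sqrt(vb)),
        n_a=na,
        n_b=nb,
        direction=f"{labels[0]} - {labels[1]}",
    )


# --------------------------------------------------------------------------
# sphericity
# --------------------------------------------------------------------------


def orthonormal_contrasts(k: int) -> np.ndarray:
    """A ``k x (k-1)`` matrix with orthonormal columns orthogonal to ones."""
    return linalg.helmert(k, full=False).T


def mauchly_and_hf(
    cov: np.ndarray, n: int, k: int, g: int = 1
) -> Tuple[float, float, float, float]:
    """Mauchly's W with its chi-square p, plus Greenhouse-Geisser and
    Huynh-Feldt epsilons, from a pooled within-participant covariance matrix.

    ``cov`` is the raw ``k x k`` covariance of the within-level variables
    (pooled over the ``g`` between cells with ``n`` participants in total);
    it is projected onto orthonormal contrasts internally.
    """
    if k < 3:
        raise InvalidParameterError("sphericity needs k >= 3 within levels")
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (k, k):
        raise InvalidParameterError("covariance shape must be (k, k)")
    C = orthonormal_contrasts(k)
    S = C.T @ cov @ C
    d = k - 1
    det = np.linalg.det(S)
    tr = np.trace(S)
    if not np.isfinite(det) or det <= 0 or tr <= 0:
        raise SingularMatrixError("contrast covariance is singular")
    W = det / (tr / d) ** d
    ne = n - g  # error degrees of freedom of the pooled covariance
    f = 1 - (2 * d**2 + d + 2) / (6 * d * ne)
    chi2 = -ne * f * np.log(W)
    dof = k * (k - 1) / 2 - 1
    p = sps.chi2.sf(chi2, dof)
    eps_gg = tr**2 / (d * np.trace(S @ S))
    eps_hf = ((ne + 1) * d * eps_gg - 2) / (d * (ne - d * eps_gg))
    eps_hf = min(float(eps_hf), 1.0)
    return float(W), float(p), float(eps_gg), float(eps_hf)


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------


def _effect_code(values: np.ndarray, name: str) -> Tuple[np.ndarray, List[str]]:
    """Sum-to-zero (deviation) coding: one column per non-reference level."""
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        raise InvalidParameterError(f"factor {name!r} needs >= 2 levels")
    cols, names = [], []
    for lev in levels[:-1]:
        x = np.where(values == lev, 1.0, np.where(values == levels[-1], -1.0, 0.0))
        cols.append(x)
        names.append(f"{name}[{lev}]")
    return np.column_stack(cols), names


def _between_design(
    design: pd.DataFrame, between: Sequence[str], covariates: Sequence[str]
) -> Tuple[np.ndarray, Dict[str, slice], List[str]]:
    """Full-factorial effect-coded design matrix with named column blocks."""
    n = len(design)
    blocks: List[np.ndarray] = [np.ones((n, 1))]
    term_slices: Dict[str, slice] = {"Intercept": slice(0, 1)}
    names = ["Intercept"]
    start = 1
    coded = {f: _effect_code(design[f].to_numpy(), f)[0] for f in between}
    for order in range(1, len(between) + 1):
        for combo in itertools.combinations(between, order):
            block = coded[combo[0]]
            for f in combo[1:]:
                # all pairwise column products between the factors
                block = np.einsum("ni,nj->nij", block, coded[f]).reshape(n, -1)
            term = ":".join(combo)
            blocks.append(block)
            term_slices[term] = slice(start, start + block.shape[1])
            names.append(term)
            start += block.shape[1]
    for c in covariates:
        vals = design[c].to_numpy(dtype=float).reshape(-1, 1)
        blocks.append(vals)
        term_slices[c] = slice(start, start + 1)
        names.append(c)
        start += 1
    X = np.hstack(blocks)
    return X, term_slices, names


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    _, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    if res.size:
        return float(res[0])
    fit = X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(np.sum((y - fit) ** 2))


def _term_ss(
    X: np.ndarray, y: np.ndarray, term_slices: Dict[str, slice]
) -> Tuple[Dict[str, float], float]:
    """Type III sums of squares by dropping each term's block from the full
    effect-coded model."""
    rss_full = _rss(X, y)
    out = {}
    for term, sl in term_slices.items():
        keep = np.ones(X.shape[1], dtype=bool)
        keep[sl] = False
        out[term] = _rss(X[:, keep], y) - rss_full
    return out, rss_full


# --------------------------------------------------------------------------
# mixed ANOVA / ANCOVA
# --------------------------------------------------------------------------


@dataclass
class AnovaResult:
    table: pd.DataFrame
    mauchly_w: float = float("nan")
    mauchly_p: float = float("nan")
    epsilon_gg: float = float("nan")
    epsilon_hf: float = float("nan")
    meta: dict = field(default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(name)
        return rows.iloc[0]


def _pivot_wide(
    data: pd.DataFrame, dv: str, within: str, subject: str
) -> pd.DataFrame:
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    missing = wide[wide.isna().any(axis=1)].index.tolist()
    if missing:
        raise UnbalancedDesignError(
            f"participants missing within-factor levels: {missing}"
        )
    return wide.sort_index()


def _subject_design(
    data: pd.DataFrame, subject: str, columns: Sequence[str], index: pd.Index
) -> pd.DataFrame:
    cols = {}
    for c in columns:
        per = data.groupby(subject)[c].nunique()
        if (per > 1).any():
            bad = per[per > 1].index.tolist()
            raise InvalidParameterError(
                f"{c!r} varies within participants {bad}; between-level values required"
            )
        cols[c] = data.groupby(subject)[c].first()
    if not cols:
        return pd.DataFrame(index=index)
    return pd.DataFrame(cols).loc[index]


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: Sequence[str],
    covariates: Sequence[str] = (),
    sphericity_alpha: float = SPHERICITY_ALPHA,
) -> AnovaResult:
    """Split-plot mixed ANOVA (optionally with between-level covariates).

    ``data`` is a long table; ``between`` factors and ``covariates`` must be
    constant within participant. Every participant must contribute every
    within level (no imputation). Type III sums of squares with sum-to-zero
    contrasts throughout.
    """
    between = list(between)
    covariates = list(covariates)
    wide = _pivot_wide(data, dv, within, subject)
    design = _subject_design(data, subject, between + covariates, wide.index)
    n, k = wide.shape
    for f in between:
        counts = design.groupby(f).size()
        if (counts < 2).any():
            raise InvalidParameterError(f"factor {f!r} has a cell with < 2 participants")

    X, term_slices, _ = _between_design(design, between, covariates)
    if np.linalg.cond(X) > _COND_LIMIT:
        raise CollinearityError("between design is ill conditioned (collinear terms)")

    rows = []
    # ---- between stratum: participant means
    yb = wide.to_numpy().mean(axis=1)
    ss_b, rss_b = _term_ss(X, yb, term_slices)
    df_err_b = n - X.shape[1]
    if df_err_b <= 0:
        raise InvalidParameterError("no residual degrees of freedom between participants")
    mse_b = rss_b / df_err_b
    # numerically-zero stratum (e.g. constant dv): flag F as undefined
    tiny_b = 1e-12 * (np.sum(yb**2) + 1.0)
    for term, sl in term_slices.items():
        if term == "Intercept":
            continue
        df1 = sl.stop - sl.start
        ss = ss_b[term]
        if ss < tiny_b:
            ss = 0.0
        F = (ss / df1) / mse_b if mse_b > tiny_b else np.nan
        p = sps.f.sf(F, df1, df_err_b) if np.isfinite(F) else np.nan
        rows.append(
            dict(effect=term, ss=ss, df1=float(df1), df2=float(df_err_b), F=F, p=p,
                 correction="none")
        )

    mauchly_w = mauchly_p = eps_gg = eps_hf = float("nan")
    if k >= 2:
        # ---- within stratum: orthonormal contrast scores
        C = orthonormal_contrasts(k)
        Yc = wide.to_numpy() @ C
        Xb, bt_slices, _ = _between_design(design, between, [])
        pb = Xb.shape[1]
        d = k - 1
        ss_within: Dict[str, float] = {t: 0.0 for t in bt_slices}
        rss_w = 0.0
        for j in range(d):
            ss_j, rss_j = _term_ss(Xb, Yc[:, j], bt_slices)
            for t, v in ss_j.items():
                ss_within[t] += v
            rss_w += rss_j
        df_err_w = d * (n - pb)
        mse_w = rss_w / df_err_w if df_err_w > 0 else np.nan

        # ---- sphericity diagnostics on the pooled within-cell covariance
        eps_applied = 1.0
        correction = "none"
        if k >= 3:
            cells = (
                design[between].astype(str).agg("|".join, axis=1)
                if between
                else pd.Series("all", index=design.index)
            )
            g = cells.nunique()
            resid = wide.to_numpy() - wide.groupby(cells).transform("mean").to_numpy()
            if n - g >= k:
                cov = resid.T @ resid / (n - g)
                try:
                    mauchly_w, mauchly_p, eps_gg, eps_hf = mauchly_and_hf(cov, n, k, g)
                    if mauchly_p < sphericity_alpha:
                        eps_applied = eps_hf
                        correction = "HF"
                except SingularMatrixError:
                    pass
        else:
            mauchly_w, eps_gg, eps_hf = 1.0, 1.0, 1.0

        for term, sl in bt_slices.items():
            df_term = 1 if term == "Intercept" else sl.stop - sl.start
            df1 = d * df_term
            label = within if term == "Intercept" else f"{term}:{within}"
            ss = ss_within[term]
            F = (ss / df1) / mse_w if np.isfinite(mse_w) and mse_w > 0 else np.nan
            df1c, df2c = df1 * eps_applied, df_err_w * eps_applied
            p = sps.f.sf(F, df1c, df2c) if np.isfinite(F) else np.nan
            rows.append(
                dict(effect=label, ss=ss, df1=df1c, df2=df2c, F=F, p=p,
                     correction=correction)
            )

    table = pd.DataFrame(rows)
    return AnovaResult(
        table=table,
        mauchly_w=mauchly_w,
        mauchly_p=mauchly_p,
        epsilon_gg=eps_gg,
        epsilon_hf=eps_hf,
        meta={
            "ss_type": "III",
            "contrasts": "sum-to-zero",
            "n_participants": n,
            "n_within_levels": k,
            "covariates": covariates,
        },
    )


def mixed_ancova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: Sequence[str],
    covariates: Sequence[str],
    **kwargs,
) -> AnovaResult:
    """Mixed ANOVA with between-level covariates in the participant stratum."""
    if not covariates:
        raise InvalidParameterError("mixed_ancova requires at least one covariate")
    return mixed_anova(
        data, dv, within, subject, between, covariates=covariates, **kwargs
    )


# --------------------------------------------------------------------------
# covariate preparation
# --------------------------------------------------------------------------


def prepare_covariates(
    metric_table: pd.DataFrame,
    design: pd.DataFrame,
    rois: Sequence[str] = ("cPRL", "cURL"),
    share_with_matched: bool = True,
) -> pd.DataFrame:
    """Participant-level ROI covariates joined onto the design table.

    ``cov_ecc`` is the mean retinotopic eccentricity of the participant's
    ROIs, shared between a patient and their matched control when one exists,
    then log-transformed and mean-centred. ``cov_size`` is the mean ROI vertex
    count, centred (no log).
    """
    sub = metric_table[metric_table["roi_label"].isin(rois)]
    per = (
        sub.drop_duplicates(["participant", "roi_label"])
        .groupby("participant")[["n_vertices", "mean_ecc"]]
        .mean()
    )
    out = design.copy()
    out["cov_size"] = per["n_vertices"].reindex(out.index)
    out["cov_ecc"] = per["mean_ecc"].reindex(out.index)
    if share_with_matched and "matched_id" in out.columns:
        for pid, row in out.iterrows():
            m = row.get("matched_id")
            if (
                row.get("diagnosis") == "HC"
                and isinstance(m, str)
                and m in out.index
            ):
                out.at[pid, "cov_ecc"] = out.at[m, "cov_ecc"]
    if (out["cov_ecc"] <= 0).any() or out[["cov_ecc", "cov_size"]].isna().any().any():
        raise InvalidParameterError("covariates must be positive and defined for all rows")
    out["cov_ecc"] = np.log(out["cov_ecc"])
    out["cov_ecc"] -= out["cov_ecc"].mean()
    out["cov_size"] = out["cov_size"] - out["cov_size"].mean()
    return out


# --------------------------------------------------------------------------
# FDR post-hocs
# --------------------------------------------------------------------------


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def posthoc_fdr(
    data: pd.DataFrame,
    dv: str,
    group: str,
    roi_col: str,
    order: Tuple[str, str] = ("MD", "HC"),
    q: float = 0.05,
    rois: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-ROI Welch t-tests with BH adjustment across the ROI family."""
    if rois is None:
        rois = list(pd.unique(data[roi_col]))
    rows = []
    for roi in rois:
        sub = data[data[roi_col] == roi]
        a = sub.loc[sub[group] == order[0], dv].to_numpy()
        b = sub.loc[sub[group] == order[1], dv].to_numpy()
        res = welch_t(a, b, labels=order)
        rows.append(
            dict(roi=roi, t=res.t, df=res.df, p=res.p,
                 mean_a=res.mean_a, mean_b=res.mean_b, direction=res.direction)
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_fdr"] < q
    return out
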