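"""Predictability screen: PCA-reduced predictor blocks, best-subset OLS with
sequential replacement, covariate adjustment, AICc ranking, and FDR across
the screen.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from microguild.stats import bh_fdr

CONDITION_LIMIT = 1e8


@dataclass
class PredictorBlock:
    """Named subjects x features predictor matrix.

    ``kind`` is ``pc_reduced`` for PCA score blocks (exactly the leading
    components as columns) or ``raw`` for untransformed feature blocks.
    """

    name: str
    frame: pd.DataFrame
    kind: str = "raw"
    loadings: pd.DataFrame | None = None
    explained_variance_ratio: np.ndarray | None = None


def pca_reduce(
    matrix: pd.DataFrame, name: str, n_components: int = 3
) -> PredictorBlock:
    """Reduce a subjects x features matrix to its leading principal components.

    Features are centered internally. Returns scores (PC1..PCn), loadings for
    interpretation, and the explained-variance ratios. Fewer components are
    returned (with a warning) when the matrix rank is limiting.
    """
    x = matrix.to_numpy(dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError("PCA input must be complete")
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("zero-variance matrix")
    n_avail = min(n_components, min(x.shape[0] - 1, x.shape[1]))
    if n_avail < n_components:
        warnings.warn(
            f"rank limits block {name!r} to {n_avail} component(s)", stacklevel=2
        )
    pca = PCA(n_components=n_avail)
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_avail)]
    return PredictorBlock(
        name=name,
        frame=pd.DataFrame(scores, index=matrix.index, columns=cols),
        kind="pc_reduced",
        loadings=pd.DataFrame(pca.components_.T, index=matrix.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class OlsFit:
    predictors: tuple[str, ...]
    beta: dict[str, float]
    se: dict[str, float]
    t_p: dict[str, float]
    r2: float
    adj_r2: float
    f_stat: float
    f_p: float
    rss: float
    n: int
    n_regressors: int  # excluding intercept
    condition_number: float
    residuals: np.ndarray


def _ols(y: np.ndarray, columns: list[tuple[str, np.ndarray]]) -> OlsFit:
    n = y.size
    names = ["intercept"] + [c[0] for c in columns]
    x = np.column_stack([np.ones(n)] + [c[1] for c in columns])
    k = x.shape[1]
    if n <= k:
        raise ValueError("not enough observations for the design")
    beta, _, rank, sv = np.linalg.lstsq(x, y, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    fitted = x @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    p_reg = k - 1
    dof = n - k
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else -np.inf
    if p_reg > 0 and dof > 0 and rss > 0 and tss > rss:
        f_stat = (r2 / p_reg) / ((1.0 - r2) / dof)
        f_p = float(sps.f.sf(f_stat, p_reg, dof))
    elif p_reg > 0 and dof > 0 and tss > 0 and rss == 0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat, f_p = 0.0, 1.0
    sigma2 = rss / dof if dof > 0 else np.nan
    try:
        xtx_inv = np.linalg.inv(x.T @ x)
        se_vec = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    except np.linalg.LinAlgError:
        se_vec = np.full(k, np.nan)
    t_p = {}
    se = {}
    for i, name in enumerate(names):
        se[name] = float(se_vec[i])
        if se_vec[i] > 0 and dof > 0:
            t_p[name] = float(2.0 * sps.t.sf(abs(beta[i] / se_vec[i]), dof))
        else:
            t_p[name] = np.nan
    predictor_names = tuple(c[0] for c in columns)
    return OlsFit(
        predictors=predictor_names,
        beta={name: float(b) for name, b in zip(names, beta)},
        se=se,
        t_p=t_p,
        r2=r2,
        adj_r2=adj_r2,
        f_stat=float(f_stat),
        f_p=f_p,
        rss=rss,
        n=n,
        n_regressors=p_reg,
        condition_number=cond,
        residuals=resid,
    )


def aicc(n: int, rss: float, k_params: int) -> float:
    """Small-sample corrected Akaike criterion for a Gaussian OLS model.

    ``AICc = n ln(rss/n) + 2k + 2k(k+1)/(n - k - 1)`` where ``k_params``
    counts the intercept, covariate, predictors, and the residual variance.
    """
    if rss <= 0:
        raise ValueError("rss must be positive")
    if n <= k_params + 1:
        raise ValueError("AICc undefined: n must exceed k_params + 1")
    return float(
        n * np.log(rss / n)
        + 2 * k_params
        + 2 * k_params * (k_params + 1) / (n - k_params - 1)
    )


def relative_aicc(values) -> np.ndarray:
    """Percent-of-worst AICc: 100 * AICc / max(AICc); lower means better.

    If any AICc is non-positive the whole grid is first shifted so its
    minimum equals one (logged), keeping the ratio well defined.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty AICc grid")
    finite = vals[np.isfinite(vals)]
    if finite.size and finite.min() <= 0:
        shift = 1.0 - finite.min()
        warnings.warn(
            f"non-positive AICc values; shifting grid by {shift:.6g} before "
            "computing relative percentages",
            stacklevel=2,
        )
        vals = vals + shift
    return 100.0 * vals / np.nanmax(vals)


@dataclass
class MlrModelResult:
    """One fitted cell of the predictability screen.

    ``model_p`` is the partial F-test p of the selected predictors over the
    covariate-only baseline (the screen's question: do the predictors explain
    the response after dose/sex adjustment). ``f_p`` is the overall F-test p
    of the final model including the covariate. ``selection_p`` is a
    selection-aware permutation p of the whole subset search; unlike the two
    F tests it stays uniform under the null despite the selection step, at a
    cost in power.
    """

    response: str
    block: str
    predictors: tuple[str, ...]
    beta: dict[str, float]
    predictor_p: dict[str, float]
    adj_r2: float
    model_p: float
    f_p: float
    selection_p: float
    aicc: float
    n: int
    q: float | None = None
    rel_aicc: float | None = None
    shapiro_p: float | None = None
    breusch_pagan_p: float | None = None


def _diagnostics(fit: OlsFit, design_cols: list[tuple[str, np.ndarray]]):
    resid = fit.residuals
    shapiro_p = float(sps.shapiro(resid).pvalue) if 3 <= resid.size <= 5000 else None
    bp_p = None
    if design_cols and resid.size > len(design_cols) + 2:
        # Breusch-Pagan: regress squared residuals on the design
        aux = _ols(resid**2, design_cols)
        lm = aux.r2 * resid.size
        bp_p = float(sps.chi2.sf(lm, len(design_cols)))
    return shapiro_p, bp_p


def _subset_pool(features: list[str], max_predictors: int) -> list[tuple[str, ...]]:
    pool = [(f,) for f in features]
    if max_predictors >= 2:
        pool += [tuple(c) for c in itertools.combinations(features, 2)]
    return pool


def _max_adj_r2_stat(
    y_matrix: np.ndarray,
    cov: np.ndarray | None,
    feat: dict[str, np.ndarray],
    subsets: list[tuple[str, ...]],
    n_cov: int,
) -> np.ndarray:
    """Max adjusted R-squared over candidate subsets, per column of y_matrix."""
    n = y_matrix.shape[0]
    y_centered = y_matrix - y_matrix.mean(axis=0, keepdims=True)
    tss = (y_centered**2).sum(axis=0)
    tss = np.where(tss > 0, tss, np.inf)
    best = np.full(y_matrix.shape[1], -np.inf)
    for subset in subsets:
        cols = [np.ones(n)]
        if cov is not None:
            cols.append(cov)
        cols.extend(feat[f] for f in subset)
        x = np.column_stack(cols)
        q, _ = np.linalg.qr(x)
        proj = q.T @ y_matrix
        rss = (y_matrix**2).sum(axis=0) - (proj**2).sum(axis=0)
        r2 = 1.0 - np.clip(rss, 0, None) / tss
        p_reg = n_cov + len(subset)
        dof = n - 1 - p_reg
        if dof <= 0:
            continue
        adj = 1.0 - (1.0 - r2) * (n - 1) / dof
        best = np.maximum(best, adj)
    return best


def selection_permutation_p(
    y: np.ndarray,
    cov: np.ndarray | None,
    feat: dict[str, np.ndarray],
    subsets: list[tuple[str, ...]],
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p value for the whole best-subset search.

    The statistic is the maximum adjusted R-squared over every candidate
    subset (the quantity the selection maximises), so the p value accounts
    for selection. The null is generated Freedman-Lane style: the response is
    regressed on intercept + covariate, and its residuals are permuted and
    added back to the fitted values before re-running the exhaustive search.
    """
    n = y.size
    n_cov = 0 if cov is None else 1
    obs = float(_max_adj_r2_stat(y[:, None], cov, feat, subsets, n_cov)[0])
    base = np.column_stack([np.ones(n)] + ([cov] if cov is not None else []))
    coef, *_ = np.linalg.lstsq(base, y, rcond=None)
    fitted = base @ coef
    resid = y - fitted
    rng = np.random.default_rng(seed)
    # argsort of uniform columns = one independent permutation per column
    perm_y = fitted[:, None] + resid[np.argsort(rng.random((n, n_perm)), axis=0)]
    null = _max_adj_r2_stat(perm_y, cov, feat, subsets, n_cov)
    exceed = int(np.count_nonzero(null >= obs - 1e-12))
    return (1 + exceed) / (n_perm + 1)


def best_subset_mlr(
    response: pd.Series,
    block: PredictorBlock,
    covariate: pd.Series | None,
    max_predictors: int = 2,
    response_name: str | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> MlrModelResult:
    """Select the best 1-2 predictors from a block by sequential replacement.

    The search starts from the best single predictor, greedily adds the best
    second, then repeatedly swaps one member for any non-member while the
    adjusted R-squared improves; the best subset of each size competes by
    adjusted R-squared. The final model is OLS of the response on intercept +
    covariate + selected predictors. Subsets whose design is numerically
    collinear (condition number above 1e8) are passed over for the
    next-best subset, with a warning.

    Three p values are reported: ``model_p`` (partial F of the selected
    predictors over the covariate-only baseline), ``f_p`` (overall F of the
    final model), and ``selection_p`` (permutation p of the whole search via
    :func:`selection_permutation_p`).
    """
    if max_predictors not in (1, 2):
        raise ValueError("max_predictors must be 1 or 2")
    subjects = response.dropna().index
    subjects = subjects.intersection(block.frame.dropna().index)
    if covariate is not None:
        subjects = subjects.intersection(covariate.dropna().index)
    subjects = list(subjects)
    n = len(subjects)
    min_n = 2 + max_predictors + 2  # intercept + covariate + predictors + df
    if n < min_n:
        raise ValueError(f"need at least {min_n} complete subjects, have {n}")
    y = response.loc[subjects].to_numpy(dtype=float)
    cov_cols: list[tuple[str, np.ndarray]] = []
    if covariate is not None:
        cov_cols.append((str(covariate.name or "covariate"),
                         covariate.loc[subjects].to_numpy(dtype=float)))
    features = list(block.frame.columns)
    feat = {f: block.frame.loc[subjects, f].to_numpy(dtype=float) for f in features}

    def fit(subset: tuple[str, ...]) -> OlsFit:
        return _ols(y, cov_cols + [(f, feat[f]) for f in subset])

    def score(subset: tuple[str, ...]) -> float:
        try:
            f = fit(subset)
        except ValueError:
            return -np.inf
        if f.condition_number > CONDITION_LIMIT:
            return -np.inf
        return f.adj_r2

    singles = sorted(((score((f,)), (f,)) for f in features), reverse=True)
    candidates = [singles[0][1]]
    if max_predictors == 2 and len(features) >= 2:
        best_single = singles[0][1][0]
        additions = sorted(
            (
                (score(tuple(sorted((best_single, f)))), tuple(sorted((best_single, f))))
                for f in features
                if f != best_single
            ),
            reverse=True,
        )
        current = additions[0][1]
        current_score = additions[0][0]
        improved = True
        while improved:
            improved = False
            for member in current:
                for cand in features:
                    if cand in current:
                        continue
                    trial = tuple(sorted(set(current) - {member} | {cand}))
                    s = score(trial)
                    if s > current_score + 1e-12:
                        current, current_score = trial, s
                        improved = True
                        break
                if improved:
                    break
        candidates.append(current)
    # best across sizes by adjusted R^2, skipping collinear designs
    ranked = sorted(((score(c), c) for c in candidates), reverse=True)
    chosen = None
    for s, c in ranked:
        if np.isfinite(s):
            chosen = c
            break
    if chosen is None:
        # fall back to exhaustive search for any well-conditioned subset
        pool = [tuple(c) for c in itertools.combinations(features, 1)]
        if max_predictors == 2:
            pool += [tuple(c) for c in itertools.combinations(features, 2)]
        ranked = sorted(((score(c), c) for c in pool), reverse=True)
        for s, c in ranked:
            if np.isfinite(s):
                chosen = c
                break
        if chosen is None:
            raise ValueError("no well-conditioned predictor subset exists")
        warnings.warn("sequential-replacement subsets were collinear; "
                      "fell back to exhaustive search", stacklevel=2)
    final = fit(chosen)
    k_params = 1 + len(cov_cols) + len(chosen) + 1  # + residual variance
    design_cols = cov_cols + [(f, feat[f]) for f in chosen]
    shapiro_p, bp_p = _diagnostics(final, design_cols)
    cov_vec = cov_cols[0][1] if cov_cols else None
    pool = _subset_pool(features, max_predictors)
    selection_p = selection_permutation_p(
        y, cov_vec, feat, pool, n_perm=n_perm, seed=seed
    )
    base = _ols(y, cov_cols) if cov_cols else _ols(y, [])
    m = len(chosen)
    dof = n - 1 - len(cov_cols) - m
    if final.rss > 0 and dof > 0 and base.rss > final.rss:
        partial_f = ((base.rss - final.rss) / m) / (final.rss / dof)
        model_p = float(sps.f.sf(partial_f, m, dof))
    elif final.rss == 0:
        model_p = 0.0
    else:
        model_p = 1.0
    return MlrModelResult(
        response=response_name or str(response.name or "response"),
        block=block.name,
        predictors=chosen,
        beta={f: final.beta[f] for f in chosen},
        predictor_p={f: final.t_p[f] for f in chosen},
        adj_r2=final.adj_r2,
        model_p=model_p,
        f_p=final.f_p,
        selection_p=selection_p,
        aicc=aicc(n, final.rss, k_params) if final.rss > 0 else -np.inf,
        n=n,
        shapiro_p=shapiro_p,
        breusch_pagan_p=bp_p,
    )


@dataclass
class MlrScreenResult:
    """Grid of fitted models over responses x predictor blocks."""

    cells: list[MlrModelResult] = field(default_factory=list)
    covariate_name: str = "dose_sex"
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "response": c.response,
                    "block": c.block,
                    "predictors": "+".join(c.predictors),
                    "beta": ";".join(f"{k}={v:.6g}" for k, v in c.beta.items()),
                    "adj_r2": c.adj_r2,
                    "p": c.model_p,
                    "f_p": c.f_p,
                    "selection_p": c.selection_p,
                    "q": c.q,
                    "aicc": c.aicc,
                    "rel_aicc": c.rel_aicc,
                    "n": c.n,
                }
            )
        return pd.DataFrame(rows)

    def rel_aicc_matrix(self) -> pd.DataFrame:
        frame = self.to_frame()
        return frame.pivot(index="block", columns="response", values="rel_aicc")

    def cell(self, response: str, block: str) -> MlrModelResult:
        for c in self.cells:
            if c.response == response and c.block == block:
                return c
        raise KeyError((response, block))


def predictability_screen(
    responses: dict[str, pd.Series],
    blocks: list[PredictorBlock],
    covariate: pd.Series | None,
    max_predictors: int = 2,
    fdr_family: str = "screen",
    n_perm: int = 999,
    seed: int = 0,
) -> MlrScreenResult:
    """Fit one best-subset model per (response, block) cell.

    BH-FDR runs over all cells of the screen (``fdr_family='screen'``) or
    within each response column (``'per_response'``); relative AICc is always
    computed per response column, so 100 marks each response's worst model.
    """
    result = MlrScreenResult(
        covariate_name=str(covariate.name) if covariate is not None else "none"
    )
    cell_index = 0
    for rname, response in responses.items():
        for block in blocks:
            if block.frame.shape[1] < 1:
                result.skipped.append((rname, block.name, "no usable features"))
                continue
            cell_index += 1
            try:
                cell = best_subset_mlr(
                    response, block, covariate, max_predictors,
                    response_name=rname, n_perm=n_perm,
                    seed=seed + 7919 * cell_index,
                )
            except ValueError as exc:
                result.skipped.append((rname, block.name, str(exc)))
                continue
            result.cells.append(cell)
    if not result.cells:
        return result
    if fdr_family == "screen":
        q = bh_fdr([c.model_p for c in result.cells])
        for c, qi in zip(result.cells, q):
            c.q = float(qi)
    elif fdr_family == "per_response":
        for rname in responses:
            cells = [c for c in result.cells if c.response == rname]
            if cells:
                q = bh_fdr([c.model_p for c in cells])
                for c, qi in zip(cells, q):
                    c.q = float(qi)
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    for rname in responses:
        cells = [c for c in result.cells if c.response == rname]
        if cells:
            rel = relative_aicc([c.aicc for c in cells])
            for c, ri in zip(cells, rel):
                c.rel_aicc = float(ri)
    return result
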