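"""Three-stage feature reduction.

1. **Stability screening** — every feature is chi-squared-tested (cases vs
   control set k) once per control set; it survives only if it reaches the
   significance level ``alpha`` in at least ``stability_fraction`` of the
   ``n_cohorts`` tests.  Features more frequent in controls than cases are
   kept with negative direction rather than discarded.
2. **Logistic-regression filter** — survivors are Wald-tested in per-feature
   univariable logistic fits (default) or one joint multivariable model; a
   feature stays if its Wald p is below ``lr_alpha``.  Univariable is the
   default because the hierarchical code levels produce near-duplicate
   columns whose joint Wald statistics are uninformative (the coefficient is
   split across near-copies).  Perfectly collinear duplicates are removed
   first; complete separation is flagged and the feature retained, never
   silently dropped.
3. **PCA** — the retained binary matrix is mean-centred (not variance-scaled:
   all features share the same 0/1 scale) and decomposed; components are kept
   up to a cumulative explained-variance target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.01
    stability_fraction: float = 0.90   # 0.90 used for the larger stratum, 0.75 for the smaller
    n_cohorts: int = 100
    lr_alpha: float = 0.01
    lr_mode: str = "univariable"       # "univariable" | "joint"
    pca_variance_target: float = 0.80
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "lr_alpha"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 < self.stability_fraction <= 1.0:
            raise ValueError("stability_fraction must be in (0, 1]")
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")
        if self.lr_mode not in ("joint", "univariable"):
            raise ValueError(f"lr_mode must be joint/univariable, got {self.lr_mode!r}")
        if not 0.0 < self.pca_variance_target <= 1.0:
            raise ValueError("pca_variance_target must be in (0, 1]")


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def chi2_tables(a, b, c, d) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Pearson chi-squared (1 df, no continuity correction) on 2x2
    tables [[a, b], [c, d]].  Returns (statistic, upper-tail p, degenerate
    mask); degenerate tables (a zero margin) get statistic 0 and p 1."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    degenerate = denom == 0
    stat = np.where(degenerate, 0.0,
                    n * (a * d - b * c) ** 2 / np.where(degenerate, 1.0, denom))
    p = np.where(degenerate, 1.0, stats.chi2.sf(stat, df=1))
    return stat, p, degenerate


def chi2_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-squared statistic and p-value for one 2x2 table."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    stat, p, _ = chi2_tables(a, b, c, d)
    return float(stat), float(p)


@dataclass
class StabilityResult:
    """Per-feature stability outcome.

    ``table`` columns: feature_key, n_pass (tests with p < alpha), direction
    (+1 enriched in cases, -1 enriched in controls, 0 equal), n_low_expected
    (tests with a cell expectation < 5, flagged not excluded), selected.
    """

    table: pd.DataFrame
    n_cohorts: int
    threshold: int

    @property
    def selected(self) -> list[str]:
        t = self.table
        return list(t.loc[t["selected"], "feature_key"])


def stability_screen(case_matrix: pd.DataFrame,
                     control_matrices: list[pd.DataFrame],
                     cfg: SelectionConfig) -> StabilityResult:
    """Chi-squared stability screen of every feature against each control set."""
    cfg.validate()
    if len(control_matrices) != cfg.n_cohorts:
        raise ValueError(f"expected {cfg.n_cohorts} control matrices, "
                         f"got {len(control_matrices)}")
    cols = case_matrix.columns
    for k, m in enumerate(control_matrices):
        if not m.columns.equals(cols):
            raise ValueError(f"control matrix {k} feature index mismatch")

    n_case = len(case_matrix)
    a = case_matrix.to_numpy().sum(axis=0).astype(float)       # cases with flag
    b = n_case - a
    n_pass = np.zeros(len(cols), dtype=int)
    n_low = np.zeros(len(cols), dtype=int)
    control_rate_sum = np.zeros(len(cols))
    for m in control_matrices:
        n_ctl = len(m)
        c = m.to_numpy().sum(axis=0).astype(float)
        d = n_ctl - c
        stat, p, degenerate = chi2_tables(a, b, c, d)
        n_pass += (p < cfg.alpha) & ~degenerate
        n = n_case + n_ctl
        expected_min = np.minimum.reduce([
            (a + b) * (a + c) / n, (a + b) * (b + d) / n,
            (c + d) * (a + c) / n, (c + d) * (b + d) / n])
        n_low += expected_min < 5
        control_rate_sum += c / n_ctl
    case_rate = a / n_case
    mean_control_rate = control_rate_sum / cfg.n_cohorts
    direction = np.sign(case_rate - mean_control_rate).astype(int)
    threshold = int(np.ceil(cfg.stability_fraction * cfg.n_cohorts - 1e-9))
    table = pd.DataFrame({
        "feature_key": cols,
        "n_pass": n_pass,
        "direction": direction,
        "n_low_expected": n_low,
        "selected": n_pass >= threshold,
    })
    return StabilityResult(table=table, n_cohorts=cfg.n_cohorts, threshold=threshold)


# ---------------------------------------------------------------------------
# logistic-regression filter
# ---------------------------------------------------------------------------

@dataclass
class LRResult:
    """``table`` columns: feature_key, coef, p_value, flag ('' | 'duplicate' |
    'separation' | 'ridge'), retained."""

    table: pd.DataFrame

    @property
    def retained(self) -> list[str]:
        t = self.table
        return list(t.loc[t["retained"], "feature_key"])


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float = 1e-3,
                 max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """L2-stabilised IRLS fit; returns (coef, standard errors).  Used only
    when the unpenalised fit fails to converge."""
    n, p = X.shape
    Xc = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = lam * np.eye(p + 1)
    pen[0, 0] = 0.0

    def objective(b: np.ndarray) -> float:
        eta = Xc @ b
        # log-lik with penalty, numerically safe via logaddexp
        return float(y @ eta - np.logaddexp(0, eta).sum() - 0.5 * b @ pen @ b)

    for _ in range(max_iter):
        eta = np.clip(Xc @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        H = Xc.T * w @ Xc + pen
        grad = Xc.T @ (y - mu) - pen @ beta
        step = np.linalg.solve(H, grad)
        # step-halving keeps Newton stable under quasi-separation
        cur = objective(beta)
        scale = 1.0
        while scale > 1e-4 and objective(beta + scale * step) < cur:
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < 1e-8:
            break
    eta = np.clip(Xc @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    cov = np.linalg.inv(Xc.T * w @ Xc + pen)
    return beta, np.sqrt(np.diag(cov))


def lr_filter(matrix: pd.DataFrame, labels: np.ndarray,
              cfg: SelectionConfig) -> LRResult:
    """Wald-test filter at ``lr_alpha`` over the stability survivors."""
    import statsmodels.api as sm

    cfg.validate()
    y = np.asarray(labels, dtype=float)
    if matrix.shape[1] == 0:
        return LRResult(pd.DataFrame(columns=["feature_key", "coef", "p_value",
                                              "flag", "retained"]))

    # deduplicate perfectly collinear (identical) columns
    dup_mask = matrix.T.duplicated(keep="first").to_numpy()
    keep_cols = list(matrix.columns[~dup_mask])
    rows = {c: {"coef": np.nan, "p_value": np.nan, "flag": "duplicate",
                "retained": False}
            for c in matrix.columns[dup_mask]}

    def fit_block(cols: list[str]) -> None:
        X = matrix[cols].to_numpy(dtype=float)
        flag = ""
        try:
            import warnings
            with warnings.catch_warnings():
                # separation / non-convergence is detected and flagged below
                warnings.simplefilter("ignore")
                res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                    disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", False):
                raise RuntimeError("no convergence")
            coef, bse = res.params, res.bse
        except Exception:
            logger.warning("logit fit unstable for %d features; "
                           "ridge-stabilised refit", len(cols))
            coef, bse = _ridge_logit(X, y)
            flag = "ridge"
        z = coef[1:] / bse[1:]
        p = 2 * stats.norm.sf(np.abs(z))
        for j, c in enumerate(cols):
            separated = abs(coef[j + 1]) > 15 or bse[j + 1] > 50
            f = "separation" if separated else flag
            rows[c] = {"coef": float(coef[j + 1]), "p_value": float(p[j]),
                       "flag": f,
                       "retained": bool(p[j] < cfg.lr_alpha or separated)}

    if cfg.lr_mode == "joint":
        fit_block(keep_cols)
    else:
        for c in keep_cols:
            fit_block([c])

    table = pd.DataFrame(
        [{"feature_key": c, **rows[c]} for c in matrix.columns])
    return LRResult(table=table)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCModel:
    """Mean-centred (unscaled) PCA over the retained binary features.

    ``components`` has one orthonormal loading vector per row, ordered by
    non-increasing explained-variance share; ``n_retained`` components reach
    the configured cumulative-variance target and are the model's score axes.
    """

    feature_names: list[str]
    mean: np.ndarray
    components: np.ndarray                 # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    n_retained: int

    def component_label(self, i: int) -> str:
        return chr(ord("A") + i) if i < 26 else f"PC{i + 1}"


def fit_pca(matrix: pd.DataFrame, cfg: SelectionConfig | None = None) -> PCModel:
    """Full-rank mean-centred PCA; retains the smallest number of components
    whose cumulative explained-variance share reaches the target."""
    from sklearn.decomposition import PCA

    cfg = cfg or SelectionConfig()
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ValueError("PCA needs at least 2 features and 3 rows")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("constant matrix: no variance to decompose")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    n_retained = int(np.searchsorted(np.cumsum(evr),
                                     cfg.pca_variance_target - 1e-12) + 1)
    n_retained = min(n_retained, len(evr))
    return PCModel(feature_names=list(matrix.columns),
                   mean=pca.mean_, components=pca.components_,
                   explained_variance_ratio=evr, n_retained=n_retained)


def align_features(model_features: list[str], matrix: pd.DataFrame) -> np.ndarray:
    """Reindex a feature matrix onto a model's feature dictionary: missing
    columns are zero, unseen columns are ignored."""
    aligned = matrix.reindex(columns=model_features, fill_value=0)
    return aligned.to_numpy(dtype=float)


def project(model: PCModel, matrix: pd.DataFrame,
            n_components: int | None = None) -> np.ndarray:
    """Component scores: (aligned data - training mean) @ loadings^T."""
    k = n_components if n_components is not None else model.n_retained
    X = align_features(model.feature_names, matrix)
    return (X - model.mean) @ model.components[:k].T


def write_pc_model(model: PCModel, outdir: str | Path) -> dict[str, Path]:
    import yaml
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loadings = pd.DataFrame(model.components.T, index=model.feature_names,
                            columns=[model.component_label(i)
                                     for i in range(model.components.shape[0])])
    loadings.insert(0, "mean", model.mean)
    paths = {"loadings": outdir / "pca_loadings.csv",
             "meta": outdir / "pca_meta.yaml"}
    loadings.to_csv(paths["loadings"], index_label="feature_key",
                    lineterminator="\r\n")
    meta = {"n_retained": model.n_retained,
            "explained_variance_ratio":
                [float(v) for v in model.explained_variance_ratio]}
    paths["meta"].write_text(yaml.safe_dump(meta))
    return paths


def read_pc_model(indir: str | Path) -> PCModel:
    import yaml
    indir = Path(indir)
    loadings = pd.read_csv(indir / "pca_loadings.csv", index_col="feature_key")
    meta = yaml.safe_load((indir / "pca_meta.yaml").read_text())
    mean = loadings.pop("mean").to_numpy()
    return PCModel(feature_names=list(loadings.index), mean=mean,
                   components=loadings.to_numpy().T,
                   explained_variance_ratio=np.array(
                       meta["explained_variance_ratio"]),
                   n_retained=int(meta["n_retained"]))


def write_stability_report(result: StabilityResult, lr: LRResult | None,
                           path: str | Path) -> None:
    t = result.table.copy()
    if lr is not None:
        t = t.merge(lr.table.rename(columns={"retained": "lr_retained",
                                             "p_value": "lr_p"}),
                    on="feature_key", how="left")
    t.to_csv(path, index=False, lineterminator="\r\n")
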