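"""GA-MLR model building and the internal/external validation battery.

The modelling response is y = log10(% inhibition at 30 µM).  Compounds are
split into training and test sets by activity-ranked sampling, a multiple
linear regression on a small descriptor subset is fitted by ordinary least
squares, and the model is judged by the usual regulatory-style battery:

* fitting: R², adjusted R²;
* internal: leave-one-out and leave-many-out cross-validated Q²,
  Y-scrambling means (R²_Yscr, Q²_Yscr);
* external: Q²_F1/F2/F3, Lin's concordance correlation coefficient,
  RMSE and MAE on held-out compounds;
* descriptor redundancy: Todeschini's multivariate K correlation index
  (Kxx) and its response increment ΔK;
* applicability domain: leverage vs standardized cross-validated residual
  (Williams plot), warning leverage h* = 3p′/n, |residual| > 2 SD outliers.

LOO prediction errors are obtained through the exact hat-matrix identity
e_loo = e / (1 − h), which equals refitting with each row removed for OLS.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QsarDataset",
    "MlrModel",
    "ValidationReport",
    "AdReport",
    "GaConfig",
    "log_transform",
    "build_dataset",
    "prune_descriptors",
    "activity_ranked_split",
    "fit_mlr",
    "q2_loo",
    "q2_lmo",
    "y_scramble",
    "external_stats",
    "kxx_delta_k",
    "k_index",
    "ga_select",
    "exhaustive_best_subset",
    "applicability_domain",
    "validate_model",
]


def log_transform(pct_inh) -> np.ndarray:
    """log10 of % inhibition; non-positive entries become NaN with a warning.

    100 % maps to 2.0 and the smallest measured value in the study (0.1 %)
    to −1.0.
    """
    arr = np.asarray(pct_inh, dtype=float)
    bad = arr <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} non-positive % inhibition value(s) excluded "
            "from the log transform",
            stacklevel=2,
        )
    out = np.full(arr.shape, np.nan)
    out[~bad] = np.log10(arr[~bad])
    return out if out.ndim else float(out)


@dataclass
class QsarDataset:
    """Descriptor matrix, log-activity response and train/test labels."""

    ids: list[str]
    X: pd.DataFrame  # n × p, unique column names
    y: pd.Series  # log10(% inh), finite
    split: pd.Series | None = None  # "train" / "test" per row

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.ids):
            raise ValueError("ids, X and y must have the same length")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate descriptor column names")
        if not np.all(np.isfinite(self.y.to_numpy(dtype=float))):
            raise ValueError("response contains non-finite values")
        if self.X.isna().to_numpy().any():
            raise ValueError("descriptor matrix contains missing values")

    @property
    def n(self) -> int:
        return len(self.ids)

    def train_mask(self) -> np.ndarray:
        if self.split is None:
            return np.ones(self.n, dtype=bool)
        return (self.split == "train").to_numpy()

    def training(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.train_mask()
        return self.X.to_numpy(dtype=float)[m], self.y.to_numpy(dtype=float)[m]

    def test(self) -> tuple[np.ndarray, np.ndarray]:
        m = ~self.train_mask()
        return self.X.to_numpy(dtype=float)[m], self.y.to_numpy(dtype=float)[m]


def build_dataset(
    compound_set, descriptors: pd.DataFrame, split: pd.Series | None = None
) -> QsarDataset:
    """Assemble a QsarDataset from a CompoundSet and its descriptor table.

    Compounds with non-positive % inhibition are dropped with a warning
    (log-undefined); the packaged study set has none.
    """
    ids, rows, ys = [], [], []
    for r in compound_set:
        if r.pct_inh_30uM <= 0:
            warnings.warn(f"{r.id}: % inh <= 0, excluded", stacklevel=2)
            continue
        ids.append(r.id)
        rows.append(descriptors.loc[r.id])
        ys.append(math.log10(r.pct_inh_30uM))
    X = pd.DataFrame(rows, index=ids)
    y = pd.Series(ys, index=ids, name="log_pct_inh")
    if split is not None:
        split = split.loc[ids]
    return QsarDataset(ids=ids, X=X, y=y, split=split)


# ---------------------------------------------------------------------------
# descriptor pruning and splitting
# ---------------------------------------------------------------------------

def prune_descriptors(
    X: pd.DataFrame,
    constant_fraction: float = 0.85,
    correlation_cutoff: float = 0.90,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Drop near-constant, all-zero and highly inter-correlated columns.

    Rules, applied in order: a column with more than ``constant_fraction``
    identical values is dropped ("constant"); an all-zero column is dropped
    ("zero"); scanning remaining pairs in column order, the *later* column of
    any pair with |Pearson r| > ``correlation_cutoff`` is dropped
    ("correlated").  Returns the reduced frame and a (column, rule) log.
    """
    if len(X) < 3:
        raise ValueError("need at least 3 rows to prune descriptors")
    removed: list[tuple[str, str]] = []
    keep: list[str] = []
    for col in X.columns:
        v = X[col]
        if (v == 0).all():
            removed.append((col, "zero"))
        elif v.value_counts(normalize=True).iloc[0] > constant_fraction:
            removed.append((col, "constant"))
        else:
            keep.append(col)
    # pairwise correlation scan, keeping the earlier column
    surviving: list[str] = []
    for col in keep:
        drop = False
        for prev in surviving:
            r = np.corrcoef(X[prev], X[col])[0, 1]
            if abs(r) > correlation_cutoff:
                removed.append((col, f"correlated(|r|>{correlation_cutoff} with {prev})"))
                drop = True
                break
        if not drop:
            surviving.append(col)
    if not surviving:
        raise ValueError("all descriptor columns were removed by pruning")
    return X[surviving], removed


def activity_ranked_split(
    y, n_bins: int = 5, seed: int = 0, test_size: int | None = None
) -> pd.Series:
    """Activity-ranked train/test split.

    Rows are ranked by response, cut into ``n_bins`` contiguous bins of
    near-equal size, and one or two members per bin are drawn (seeded) for
    the test set.  By default the test size is round(n/5) clipped to
    [n_bins, 2·n_bins], which gives the study's 29 train / 7 test for n=36;
    the bins contributing a second member are chosen at random.
    """
    y = pd.Series(y)
    n = len(y)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} rows, got {n}")
    if test_size is None:
        test_size = int(np.clip(round(n / 5), n_bins, 2 * n_bins))
    if not n_bins <= test_size <= 2 * n_bins:
        raise ValueError("test_size must draw 1-2 compounds per bin")
    rng = np.random.default_rng(seed)
    order = np.argsort(y.to_numpy(), kind="stable")
    bins = np.array_split(order, n_bins)
    doubles = set(rng.choice(n_bins, size=test_size - n_bins, replace=False))
    test_idx: list[int] = []
    for b, members in enumerate(bins):
        k = 2 if b in doubles else 1
        test_idx.extend(rng.choice(members, size=min(k, len(members)), replace=False))
    labels = np.full(n, "train", dtype=object)
    labels[np.array(test_idx, dtype=int)] = "test"
    return pd.Series(labels, index=y.index, name="split")


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------

@dataclass
class MlrModel:
    """Fitted (or published) multiple linear regression model."""

    intercept: float
    coefficients: dict[str, float]
    training_ids: list[str] = field(default_factory=list)
    training_X: pd.DataFrame | None = None  # for leverages / AD

    @property
    def p_prime(self) -> int:
        """Number of adjustable parameters (coefficients + intercept)."""
        return len(self.coefficients) + 1

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, X) -> np.ndarray:
        """Predict log10(% inh) for rows of X (DataFrame or dict-like)."""
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.coefficients if c not in X.columns]
            if missing:
                raise KeyError(f"descriptor columns missing: {missing}")
            M = X[self.descriptor_names].to_numpy(dtype=float)
        else:
            M = np.atleast_2d(np.asarray(X, dtype=float))
        b = np.array([self.coefficients[c] for c in self.descriptor_names])
        return self.intercept + M @ b


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    A = _design(X)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {A.shape[1]}): "
            "collinear descriptor columns"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def fit_mlr(X, y, names: list[str] | None = None, ids: list[str] | None = None) -> MlrModel:
    """Ordinary least squares via a rank-checked QR/SVD solve.

    ``X`` may be a DataFrame (column names become coefficient names) or a
    plain array with ``names``.  Exact on noiseless data.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        ids = ids if ids is not None else [str(i) for i in X.index]
        Xa = X.to_numpy(dtype=float)
        train_X = X
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        names = names or [f"x{k}" for k in range(Xa.shape[1])]
        ids = ids or [str(i) for i in range(len(Xa))]
        train_X = pd.DataFrame(Xa, columns=names, index=ids)
    ya = np.asarray(y, dtype=float)
    if len(Xa) <= Xa.shape[1] + 1:
        raise ValueError("need more training rows than adjustable parameters")
    beta = _ols(Xa, ya)
    return MlrModel(
        intercept=float(beta[0]),
        coefficients=dict(zip(names, map(float, beta[1:]))),
        training_ids=list(ids),
        training_X=train_X,
    )


def r_squared(X, y, adjusted: bool = False) -> float:
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    beta = _ols(Xa, ya)
    resid = ya - _design(Xa) @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if adjusted:
        n, p = Xa.shape
        r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2


def _hat_diag(X: np.ndarray) -> np.ndarray:
    A = _design(X)
    q, _ = np.linalg.qr(A)
    return np.sum(q * q, axis=1)


def _loo_residuals(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact LOO prediction residuals via e/(1−h)."""
    A = _design(X)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    e = y - A @ beta
    h = _hat_diag(X)
    return e / (1.0 - h)


def q2_loo(X, y) -> float:
    """Leave-one-out cross-validated explained variance 1 − PRESS/SS_tot."""
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(Xa) <= Xa.shape[1] + 2:
        raise ValueError("too few rows for leave-one-out validation")
    press = float(np.sum(_loo_residuals(Xa, ya) ** 2))
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    return 1.0 - press / ss_tot


def q2_lmo(
    X, y, leave_fraction: float = 0.3, iterations: int = 1000, seed: int = 0
) -> float:
    """Leave-many-out Q²: mean over seeded random exclusions.

    Each iteration refits without a ``leave_fraction`` share of the rows and
    scores 1 − Σ(y−ŷ)²/Σ(y−ȳ)² on the excluded rows, with ȳ the full
    training mean.  When the exclusion size is one row the rows are
    enumerated once each, which reproduces Q²_LOO exactly.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(Xa)
    n_out = max(1, int(round(leave_fraction * n)))
    ybar = ya.mean()
    ss = float(np.sum((ya - ybar) ** 2))
    if n_out == 1:
        press = float(np.sum(_loo_residuals(Xa, ya) ** 2))
        return 1.0 - press / ss
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(iterations):
        out = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out] = False
        beta = _ols(Xa[mask], ya[mask])
        pred = _design(Xa[out]) @ beta
        num = float(np.sum((ya[out] - pred) ** 2))
        den = float(np.sum((ya[out] - ybar) ** 2))
        if den > 0:
            scores.append(1.0 - num / den)
    return float(np.mean(scores))


def y_scramble(
    X,
    y,
    n_scrambles: int = 500,
    seed: int = 0,
    statistic: str = "refit",
    permutations=None,
) -> tuple[float, float]:
    """Mean R² and Q²_LOO over response permutations.

    ``statistic="refit"`` (default) refits the model on each permuted
    response and averages the resulting R² and Q²_LOO — the classical
    chance-correlation check.  ``statistic="correlation"`` instead averages
    the squared Pearson correlation between permuted and original responses,
    a scrambling diagnostic that tends to ~1/(n−1) regardless of the model.
    ``permutations`` overrides the random draws with explicit index arrays
    (the identity permutation reproduces the unscrambled statistics).
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(ya)
    if permutations is None:
        draws = [rng.permutation(n) for _ in range(n_scrambles)]
    else:
        draws = [np.asarray(p, dtype=int) for p in permutations]
    if statistic == "correlation":
        r2s = [np.corrcoef(ya, ya[p])[0, 1] ** 2 for p in draws]
        m = float(np.mean(r2s))
        return m, m
    if statistic != "refit":
        raise ValueError(f"unknown statistic {statistic!r}")
    # hat matrix depends on X only, so residual projections are reusable
    A = _design(Xa)
    q, _ = np.linalg.qr(A)
    h = np.sum(q * q, axis=1)
    r2s, q2s = [], []
    for p in draws:
        yp = ya[p]
        fit = q @ (q.T @ yp)
        e = yp - fit
        ss_tot = float(np.sum((yp - yp.mean()) ** 2))
        r2s.append(1.0 - float(e @ e) / ss_tot)
        press = float(np.sum((e / (1.0 - h)) ** 2))
        q2s.append(1.0 - press / ss_tot)
    return float(np.mean(r2s)), float(np.mean(q2s))


# ---------------------------------------------------------------------------
# external validation metrics
# ---------------------------------------------------------------------------

def concordance_ccc(y_obs, y_pred) -> float:
    """Lin's concordance correlation coefficient."""
    yo = np.asarray(y_obs, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if len(yo) < 2:
        raise ValueError("CCC needs at least 2 observations")
    do, dp = yo - yo.mean(), yp - yp.mean()
    num = 2.0 * float(np.sum(dp * do))
    den = float(np.sum(dp**2) + np.sum(do**2) + len(yo) * (yp.mean() - yo.mean()) ** 2)
    return num / den


def external_stats(
    y_test, y_pred, y_train
) -> dict[str, float]:
    """External predictivity metrics: Q²_F1/F2/F3, CCC, RMSE, MAE, R²_ext."""
    yt = np.asarray(y_test, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    ytr = np.asarray(y_train, dtype=float)
    if len(yt) == 0:
        raise ValueError("empty test set")
    sse = float(np.sum((yt - yp) ** 2))
    out = {
        "Q2_F1": 1.0 - sse / float(np.sum((yt - ytr.mean()) ** 2)),
        "Q2_F2": 1.0 - sse / float(np.sum((yt - yt.mean()) ** 2)),
        "Q2_F3": 1.0
        - (sse / len(yt))
        / (float(np.sum((ytr - ytr.mean()) ** 2)) / len(ytr)),
        "RMSE_ext": math.sqrt(sse / len(yt)),
        "MAE_ext": float(np.mean(np.abs(yt - yp))),
        "CCC_ext": concordance_ccc(yt, yp),
    }
    if len(yt) >= 2 and np.std(yp) > 0:
        out["R2_ext"] = float(np.corrcoef(yt, yp)[0, 1] ** 2)
    else:
        out["R2_ext"] = float("nan")
    return out


def k_index(M: np.ndarray) -> float:
    """Todeschini K multivariate correlation index of a column matrix.

    K = Σ_j |λ_j/Σλ − 1/p| / (2(p−1)/p) over eigenvalues of the correlation
    matrix: 0 for mutually orthogonal columns, 1 for full collinearity.
    """
    M = np.asarray(M, dtype=float)
    p = M.shape[1]
    if p < 2:
        raise ValueError("K index needs at least 2 columns")
    sd = M.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance column in K index input")
    corr = np.corrcoef(M, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    frac = lam / lam.sum()
    return float(np.sum(np.abs(frac - 1.0 / p)) / (2.0 * (p - 1) / p))


def kxx_delta_k(X, y) -> tuple[float, float]:
    """Kxx over descriptors and ΔK = Kxy − Kxx with the response appended."""
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    kxx = k_index(Xa)
    kxy = k_index(np.column_stack([Xa, ya]))
    return kxx, kxy - kxx


# ---------------------------------------------------------------------------
# genetic-algorithm descriptor selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm settings for k-subset descriptor selection."""

    population: int = 100
    generations: int = 300
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1
    k: int = 4
    seed: int = 0
    tournament: int = 2
    elitism: int = 1

    def __post_init__(self) -> None:
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.k < 1:
            raise ValueError("model size k must be >= 1")


def _subset_q2(X: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    sub = X[:, list(cols)]
    try:
        return q2_loo(sub, y)
    except np.linalg.LinAlgError:
        return -np.inf


def exhaustive_best_subset(
    X, y, k: int, top_n: int = 10
) -> list[tuple[tuple[int, ...], float]]:
    """All C(p,k) subsets ranked by Q²_LOO (brute-force oracle)."""
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    scored = [
        (cols, _subset_q2(Xa, ya, cols))
        for cols in itertools.combinations(range(Xa.shape[1]), k)
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:top_n]


def ga_select(X, y, cfg: GaConfig = GaConfig(), top_n: int = 10):
    """Select k descriptor columns maximising Q²_LOO with a genetic algorithm.

    Chromosomes are k-subsets of column indices.  Tournament selection,
    uniform membership crossover repaired to size k, per-gene swap mutation
    and single-individual elitism; fully reproducible from the seed.  When
    the search space C(p, k) is at most 2000 subsets the exhaustive scan is
    returned instead (it is both cheaper and exact).

    Returns a list of (column-index tuple, Q²_LOO), best first.
    """
    if isinstance(X, pd.DataFrame):
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    p = Xa.shape[1]
    k = cfg.k
    if p < k:
        raise ValueError(f"descriptor pool ({p}) smaller than model size {k}")
    if math.comb(p, k) <= 2000:
        return exhaustive_best_subset(Xa, ya, k, top_n)

    rng = np.random.default_rng(cfg.seed)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(cols: tuple[int, ...]) -> float:
        if cols not in cache:
            cache[cols] = _subset_q2(Xa, ya, cols)
        return cache[cols]

    def random_subset() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(p, size=k, replace=False)))

    def repair(genes: set[int]) -> tuple[int, ...]:
        genes = set(genes)
        while len(genes) > k:
            genes.remove(int(rng.choice(sorted(genes))))
        while len(genes) < k:
            genes.add(int(rng.integers(p)))
        return tuple(sorted(genes))

    pop = [random_subset() for _ in range(cfg.population)]
    for _ in range(cfg.generations):
        scored = sorted(pop, key=fitness, reverse=True)
        nxt = scored[: cfg.elitism]
        while len(nxt) < cfg.population:
            parents = []
            for _ in range(2):
                contenders = [pop[int(i)] for i in rng.integers(len(pop), size=cfg.tournament)]
                parents.append(max(contenders, key=fitness))
            if rng.random() < cfg.crossover_prob:
                common = set(parents[0]) & set(parents[1])
                rest = list(set(parents[0]) ^ set(parents[1]))
                take = [g for g in rest if rng.random() < 0.5]
                child = repair(common | set(take))
            else:
                child = parents[0]
            genes = set(child)
            for gene in list(genes):
                if rng.random() < cfg.mutation_prob:
                    genes.discard(gene)
                    genes.add(int(rng.integers(p)))
            nxt.append(repair(genes))
        pop = nxt
    ranked = sorted(set(pop) | set(cache), key=lambda c: (-fitness(c), c))
    return [(cols, fitness(cols)) for cols in ranked[:top_n]]


# ---------------------------------------------------------------------------
# applicability domain
# ---------------------------------------------------------------------------

@dataclass
class AdReport:
    """Williams-plot data: leverages, warning leverage, CV residuals, flags."""

    ids: list[str]
    leverages: np.ndarray
    h_star: float
    std_cv_residuals: np.ndarray
    is_training: np.ndarray
    outlier: np.ndarray  # |std cv residual| > 2
    outside_domain: np.ndarray  # leverage > h*

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "leverage": self.leverages,
                "std_cv_residual": self.std_cv_residuals,
                "training": self.is_training,
                "outlier": self.outlier,
                "outside_domain": self.outside_domain,
            },
            index=pd.Index(self.ids, name="id"),
        )

    def williams_plot(self, path=None):
        """Render the Williams plot (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        tr = self.is_training
        ax.scatter(self.leverages[tr], self.std_cv_residuals[tr], label="training")
        if (~tr).any():
            ax.scatter(
                self.leverages[~tr], self.std_cv_residuals[~tr],
                marker="^", label="test",
            )
        ax.axvline(self.h_star, ls="--", c="k", lw=1)
        for yv in (-2, 2):
            ax.axhline(yv, ls=":", c="grey", lw=1)
        ax.set_xlabel("leverage h")
        ax.set_ylabel("standardized CV residual")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def applicability_domain(
    model: MlrModel, ds: QsarDataset, residual_sd: float | None = None
) -> AdReport:
    """Leverage/residual applicability domain of a fitted model.

    Leverages are h_i = x_i (XᵀX)⁻¹ x_iᵀ with an intercept column, using the
    model's training rows; the warning leverage is h* = 3p′/n over the n
    training compounds.  Cross-validated (LOO) residuals of the training
    rows, and plain prediction residuals of test rows, are standardized by
    the training LOO residual standard deviation; |value| > 2 flags a
    response outlier and h > h* flags a compound outside the structural
    domain.
    """
    if model.training_X is None:
        raise ValueError("model carries no training descriptor matrix")
    names = model.descriptor_names
    Xtr = model.training_X[names].to_numpy(dtype=float)
    n_train = len(Xtr)
    A = _design(Xtr)
    xtx_inv = np.linalg.inv(A.T @ A)
    h_star = 3.0 * model.p_prime / n_train

    Xall = ds.X[names].to_numpy(dtype=float)
    yall = ds.y.to_numpy(dtype=float)
    Aall = _design(Xall)
    lev = np.einsum("ij,jk,ik->i", Aall, xtx_inv, Aall)

    train_ids = set(model.training_ids)
    is_tr = np.array([i in train_ids for i in ds.ids])

    ytr = ds.y.loc[[i for i in ds.ids if i in train_ids]].to_numpy(dtype=float)
    loo = _loo_residuals(Xtr, ytr)
    sd = residual_sd if residual_sd is not None else float(np.std(loo, ddof=0))

    resid = np.empty(ds.n)
    loo_map = dict(zip([i for i in ds.ids if i in train_ids], loo))
    pred = model.predict(ds.X)
    for k, cid in enumerate(ds.ids):
        resid[k] = loo_map[cid] if cid in loo_map else yall[k] - pred[k]
    std_resid = resid / sd

    return AdReport(
        ids=list(ds.ids),
        leverages=lev,
        h_star=h_star,
        std_cv_residuals=std_resid,
        is_training=is_tr,
        outlier=np.abs(std_resid) > 2.0,
        outside_domain=lev > h_star,
    )


# ---------------------------------------------------------------------------
# full validation battery
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Every named statistic of the model-validation battery."""

    R2: float
    R2_adj: float
    Q2_LOO: float
    Q2_LMO: float
    R2_Yscr: float
    Q2_Yscr: float
    Q2_F1: float
    Q2_F2: float
    Q2_F3: float
    CCC_ext: float
    RMSE_ext: float
    MAE_ext: float
    R2_ext: float
    Kxx: float
    delta_K: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def validate_model(
    ds: QsarDataset,
    lmo_fraction: float = 0.3,
    lmo_iterations: int = 1000,
    n_scrambles: int = 500,
    seed: int = 0,
) -> tuple[MlrModel, ValidationReport]:
    """Fit on the training rows and run the complete validation battery."""
    m = ds.train_mask()
    Xtr = ds.X.loc[m]
    ytr = ds.y.loc[m]
    model = fit_mlr(Xtr, ytr, ids=[i for i, t in zip(ds.ids, m) if t])
    Xa, ya = Xtr.to_numpy(dtype=float), ytr.to_numpy(dtype=float)
    r2 = r_squared(Xa, ya)
    r2a = r_squared(Xa, ya, adjusted=True)
    q2 = q2_loo(Xa, ya)
    q2m = q2_lmo(Xa, ya, lmo_fraction, lmo_iterations, seed=seed)
    r2ys, q2ys = y_scramble(Xa, ya, n_scrambles=n_scrambles, seed=seed)
    kxx, dk = kxx_delta_k(Xa, ya)
    if (~m).any():
        Xte, yte = ds.test()
        ext = external_stats(yte, model.predict(ds.X.loc[~m]), ya)
    else:
        ext = {k: float("nan") for k in
               ("Q2_F1", "Q2_F2", "Q2_F3", "CCC_ext", "RMSE_ext", "MAE_ext", "R2_ext")}
    report = ValidationReport(
        R2=r2, R2_adj=r2a, Q2_LOO=q2, Q2_LMO=q2m,
        R2_Yscr=r2ys, Q2_Yscr=q2ys,
        Q2_F1=ext["Q2_F1"], Q2_F2=ext["Q2_F2"], Q2_F3=ext["Q2_F3"],
        CCC_ext=ext["CCC_ext"], RMSE_ext=ext["RMSE_ext"], MAE_ext=ext["MAE_ext"],
        R2_ext=ext["R2_ext"], Kxx=kxx, delta_K=dk,
    )
    return model, report
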