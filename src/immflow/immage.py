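"""IMM-AGE flow score: diffusion-map pseudotime over 8 subset frequencies.

The score places each sample along a one-dimensional immune-ageing trajectory
learned from eight adaptive-immune features (total T cells, naive CD4,
effector memory CD4 and CD8, EMRA CD8, CD28- CD8, CD57+ CD8, regulatory
T cells).  Pipeline:

1. exclude samples missing any required feature;
2. standardize each feature by its 10% two-tailed trimmed mean and SD over
   the pooled analysis set;
3. build a diffusion map (Gaussian kernel, anisotropic density normalization
   with alpha = 1, row-stochastic Markov matrix, eigendecomposition);
4. root the trajectory at the sample with the highest CD28-positive fraction,
   i.e. the minimum CD28- CD8 frequency;
5. score each sample by its diffusion distance from the root and min-max
   scale to [0, 1] (root = 0, farthest sample = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

__all__ = [
    "IMMAGE_FEATURES",
    "ROOT_FEATURE",
    "ImmAgeConfig",
    "ImmAgeResult",
    "ImmAgeScorer",
    "DegenerateFeatureError",
    "InsufficientSamplesError",
    "trimmed_standardize",
    "build_diffusion_map",
    "select_root",
    "pseudotime_scores",
    "compute_immage",
]

#: the eight required panel features, in canonical order
IMMAGE_FEATURES: tuple[str, ...] = (
    "tcell_of_lymphs", "cd4_naive", "cd4_em", "cd8_em",
    "cd8_emra", "cd8_cd28neg", "cd8_cd57pos", "treg_of_cd4",
)
#: trajectory root = argmin of this feature (max CD28-positive fraction)
ROOT_FEATURE = "cd8_cd28neg"

MIN_SAMPLES = 8


class DegenerateFeatureError(ValueError):
    """A feature has zero trimmed SD (constant after trimming)."""


class InsufficientSamplesError(ValueError):
    """Fewer complete samples than the embedding requires."""


def trimmed_standardize(
    values, trim_fraction: float = 0.1
) -> tuple[np.ndarray, float, float]:
    """Standardize by the two-tailed trimmed mean and sample SD.

    With n values and ``k = floor(trim_fraction * n)``, the lowest and highest
    k order statistics are removed; the remaining values give the trimmed mean
    and the n-1-denominator SD, by which *every* original value is centred and
    scaled.

    Returns ``(standardized, trimmed_mean, trimmed_sd)``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError(f"need a 1-D vector of length >= 3, got shape {x.shape}")
    if not (0.0 <= trim_fraction < 0.5):
        raise ValueError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite (exclude missing samples upstream)")
    n = x.size
    k = int(np.floor(trim_fraction * n))
    core = np.sort(x)[k: n - k]
    mean = float(core.mean())
    sd = float(core.std(ddof=1))
    if sd == 0.0:
        raise DegenerateFeatureError("trimmed set is constant (trimmed SD = 0)")
    return (x - mean) / sd, mean, sd


def _bandwidth(dists: np.ndarray, rule) -> float:
    if isinstance(rule, (int, float)):
        if rule <= 0:
            raise ValueError(f"fixed bandwidth must be > 0, got {rule}")
        return float(rule)
    if rule == "median":
        nz = dists[dists > 0]
        if nz.size == 0:
            raise DegenerateFeatureError("all pairwise distances are zero")
        return float(np.median(nz))
    raise ValueError(f"unknown bandwidth rule: {rule!r}")


def build_diffusion_map(
    X: np.ndarray,
    n_components: int = 3,
    diffusion_time: int = 1,
    bandwidth="median",
    alpha: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Diffusion-map embedding of standardized samples.

    Gaussian kernel ``w_ij = exp(-d_ij^2 / (2 sigma^2))`` on Euclidean
    distances, density-normalized ``k_ij = w_ij / (q_i q_j)^alpha`` (alpha = 1
    removes sampling-density bias), row-normalized to a Markov matrix and
    eigendecomposed via the symmetric conjugate.  Returns the non-increasing
    non-unit eigenvalues and the embedding: right eigenvectors scaled by
    ``eigenvalue ** diffusion_time``.  Deterministic up to per-component sign;
    the sign is fixed so the largest-magnitude entry of each component is
    positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    n = X.shape[0]
    if n < MIN_SAMPLES:
        raise InsufficientSamplesError(f"need >= {MIN_SAMPLES} samples, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in feature matrix")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if diffusion_time < 1:
        raise ValueError("diffusion_time must be >= 1")

    D = squareform(pdist(X))
    sigma = _bandwidth(D, bandwidth)
    W = np.exp(-(D ** 2) / (2.0 * sigma ** 2))

    q = W.sum(axis=1)
    K = W / np.outer(q, q) ** alpha
    d = K.sum(axis=1)
    inv_sqrt_d = 1.0 / np.sqrt(d)
    S = K * np.outer(inv_sqrt_d, inv_sqrt_d)  # symmetric conjugate of the Markov matrix
    evals, evecs = eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    # drop the trivial unit eigenpair (constant right eigenvector)
    n_keep = min(n_components, n - 1)
    lam = evals[1: 1 + n_keep]
    psi = evecs[:, 1: 1 + n_keep] * inv_sqrt_d[:, None]
    # unit-norm right eigenvectors with a deterministic sign
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    for c in range(psi.shape[1]):
        if psi[np.argmax(np.abs(psi[:, c])), c] < 0:
            psi[:, c] = -psi[:, c]

    embedding = psi * (lam[None, :] ** diffusion_time)
    return lam, embedding


def select_root(root_values: pd.Series, rule: str = "min_cd28neg") -> str:
    """Pick the trajectory root.

    Default: the sample whose CD28- CD8 frequency is minimal (the most
    CD28-positive, least senescent sample); ties break to the
    lexicographically smallest sample id.  ``rule="explicit:<id>"`` forces a
    given sample.
    """
    if rule.startswith("explicit:"):
        rid = rule.split(":", 1)[1]
        if rid not in root_values.index:
            raise KeyError(f"explicit root {rid!r} not among retained samples")
        return rid
    if rule != "min_cd28neg":
        raise ValueError(f"unknown root rule: {rule!r}")
    v = root_values.astype(float)
    if v.isna().any():
        raise ValueError("root feature missing for retained samples")
    m = v.min()
    return sorted(v.index[v == m])[0]


def pseudotime_scores(embedding: np.ndarray, root_index: int) -> np.ndarray:
    """Diffusion distance of every sample from the root (root scores 0)."""
    emb = np.asarray(embedding, dtype=float)
    if not (0 <= root_index < emb.shape[0]):
        raise IndexError(f"root index {root_index} out of range")
    return np.linalg.norm(emb - emb[root_index], axis=1)


@dataclass
class ImmAgeConfig:
    """Tunable parameters of the scoring pipeline."""

    trim_fraction: float = 0.1
    n_components: int = 3
    diffusion_time: int = 1
    kernel_bandwidth: str | float = "median"  # "median" or a fixed sigma
    alpha: float = 1.0
    root_rule: str = "min_cd28neg"
    features: tuple[str, ...] = IMMAGE_FEATURES


@dataclass
class ImmAgeResult:
    """Scores plus the diagnostics that produced them."""

    scores: pd.Series
    root_id: str
    excluded_ids: list[str]
    eigenvalues: np.ndarray
    embedding: pd.DataFrame
    trimmed_means: dict[str, float] = field(default_factory=dict)
    trimmed_sds: dict[str, float] = field(default_factory=dict)
    config: ImmAgeConfig = field(default_factory=ImmAgeConfig)


class ImmAgeScorer(BaseEstimator):
    """Cohort-level immune-ageing pseudotime scorer (sklearn estimator).

    ``fit`` learns the trajectory from a panel table (rows = samples, columns
    include the eight required subset frequencies) and stores per-sample
    scores; ``fit_transform`` returns them as an array aligned with the
    retained rows.  Scoring is transductive — the embedding is defined only
    over the fitted cohort, so there is no out-of-sample ``transform``.

    Attributes set by ``fit``: ``scores_`` (Series in [0, 1]), ``root_id_``,
    ``excluded_ids_``, ``eigenvalues_``, ``embedding_``, ``result_``.
    """

    def __init__(
        self,
        trim_fraction: float = 0.1,
        n_components: int = 3,
        diffusion_time: int = 1,
        kernel_bandwidth="median",
        alpha: float = 1.0,
        root_rule: str = "min_cd28neg",
        features: tuple[str, ...] = IMMAGE_FEATURES,
    ):
        self.trim_fraction = trim_fraction
        self.n_components = n_components
        self.diffusion_time = diffusion_time
        self.kernel_bandwidth = kernel_bandwidth
        self.alpha = alpha
        self.root_rule = root_rule
        self.features = features

    def fit(self, X: pd.DataFrame, y=None):
        panels = self._as_frame(X)
        missing_cols = [f for f in self.features if f not in panels.columns]
        if missing_cols:
            raise KeyError(f"panel table lacks required features: {missing_cols}")
        feats = panels.loc[:, list(self.features)].astype(float)

        complete = feats.notna().all(axis=1)
        self.excluded_ids_ = list(feats.index[~complete])
        retained = feats.loc[complete]
        if len(retained) < MIN_SAMPLES:
            raise InsufficientSamplesError(
                f"only {len(retained)} complete samples "
                f"(need >= {MIN_SAMPLES}); excluded: {self.excluded_ids_}"
            )

        Z = np.empty(retained.shape)
        self.trimmed_means_, self.trimmed_sds_ = {}, {}
        for j, name in enumerate(self.features):
            try:
                Z[:, j], m, s = trimmed_standardize(
                    retained[name].to_numpy(), self.trim_fraction
                )
            except DegenerateFeatureError as err:
                raise DegenerateFeatureError(f"feature {name!r}: {err}") from err
            self.trimmed_means_[name], self.trimmed_sds_[name] = m, s

        lam, emb = build_diffusion_map(
            Z,
            n_components=self.n_components,
            diffusion_time=self.diffusion_time,
            bandwidth=self.kernel_bandwidth,
            alpha=self.alpha,
        )

        root_col = self.features.index(ROOT_FEATURE) if ROOT_FEATURE in self.features else None
        if self.root_rule == "min_cd28neg" and root_col is None:
            raise ValueError(f"root rule needs feature {ROOT_FEATURE!r}")
        root_series = retained[ROOT_FEATURE] if root_col is not None else retained.iloc[:, 0]
        root_id = select_root(root_series, self.root_rule)
        root_index = int(np.flatnonzero(retained.index == root_id)[0])

        raw = pseudotime_scores(emb, root_index)
        rmax = raw.max()
        if rmax == 0.0:
            raise DegenerateFeatureError("all samples coincide; pseudotime undefined")
        scaled = raw / rmax  # raw min is the root at 0, so this is min-max scaling

        self.scores_ = pd.Series(scaled, index=retained.index, name="immage_score")
        self.root_id_ = root_id
        self.eigenvalues_ = lam
        self.embedding_ = pd.DataFrame(
            emb, index=retained.index,
            columns=[f"DC{i + 1}" for i in range(emb.shape[1])],
        )
        self.result_ = ImmAgeResult(
            scores=self.scores_, root_id=root_id, excluded_ids=self.excluded_ids_,
            eigenvalues=lam, embedding=self.embedding_,
            trimmed_means=self.trimmed_means_, trimmed_sds=self.trimmed_sds_,
            config=ImmAgeConfig(
                self.trim_fraction, self.n_components, self.diffusion_time,
                self.kernel_bandwidth, self.alpha, self.root_rule,
                tuple(self.features),
            ),
        )
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_.to_numpy()

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            df = X
            if "subject_id" in df.columns:
                df = df.set_index("subject_id")
            return df
        raise TypeError(
            "expected a pandas DataFrame of panel frequencies "
            "(rows = samples, subject_id as index or column)"
        )


def compute_immage(panels, config: ImmAgeConfig | None = None) -> ImmAgeResult:
    """Run the full scoring pipeline on a panel table or list of panels."""
    from .phenotype import PhenotypePanel

    if isinstance(panels, list) and panels and isinstance(panels[0], PhenotypePanel):
        panels = pd.DataFrame(
            [{"subject_id": p.subject_id, **p.frequencies} for p in panels]
        )
    cfg = config or ImmAgeConfig()
    scorer = ImmAgeScorer(
        trim_fraction=cfg.trim_fraction, n_components=cfg.n_components,
        diffusion_time=cfg.diffusion_time, kernel_bandwidth=cfg.kernel_bandwidth,
        alpha=cfg.alpha, root_rule=cfg.root_rule, features=tuple(cfg.features),
    )
    scorer.fit(panels)
    return scorer.result_
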