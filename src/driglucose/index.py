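"""The deprivation/greenspace risk index: class-balanced PCA with diagnostics.

The index collapses the 15 distance-weighted exposure variables (11 census
SES + 4 NDVI metrics) into one score per location. Because diabetes cases
are ~10% of the cohort, calibration sets are first balanced by undersampling
the majority class and SMOTE-augmenting the minority; a PCA is fitted on the
correlation structure of each balanced set, the sign-aligned first-component
loadings are averaged across sets, near-zero variables are pruned, and the
weighted z-score sum is rescaled linearly to [-1, 1] with high scores
oriented towards deprived / low-greenspace conditions.

``DiabetesRiskIndex`` is the model object; ``fit`` returns an
:class:`IndexModelResults` carrying the loadings, diagnostics and scoring
parameters. ``published_model`` ships the printed loadings of the original
study as a ready-made results object that only needs calibration data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import ALL_VARIABLES, NDVI_METRICS, SES_VARIABLES

#: Published first-component loadings (variable weights) of the original
#: index, as printed by the study that introduced it. With this orientation
#: the deprivation-anchor variable (government transfer payments) loads
#: negatively, so scoring applies orientation -1 to make high = deprived.
PUBLISHED_LOADINGS: dict[str, float] = {
    "transfer_payments_pct": -0.35,
    "lone_parent_pct": -0.32,
    "income_household_median": 0.31,
    "low_income_prevalence": -0.30,
    "unemployment_pct": -0.29,
    "no_degree_pct": -0.29,
    "ndvi_median": 0.26,
    "ndvi_p5": 0.26,
    "ndvi_p95": 0.25,
    "income_individual_mean": 0.24,
    "dwellings_owned_pct": 0.24,
    "dwellings_rented_pct": -0.24,
    "labour_participation_pct": 0.12,
    "commute_active_pct": -0.10,
    "ndvi_sd": -0.02,
}

VARIANT_VARIABLES: dict[str, tuple[str, ...]] = {
    "combined": ALL_VARIABLES,
    "ses_only": SES_VARIABLES,
    "greenspace_only": NDVI_METRICS,
}

DEFAULT_ANCHOR = "transfer_payments_pct"


class DegenerateVariableError(ValueError):
    """A column has zero variance and cannot be standardized."""


class ScoringError(ValueError):
    pass


def standardize(matrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scores with sample (n-1) SDs; returns (Z, means, sds)."""
    X = np.asarray(matrix, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds <= 0)
    if bad.size:
        cols = list(matrix.columns[bad]) if hasattr(matrix, "columns") else bad.tolist()
        raise DegenerateVariableError(f"constant column(s): {cols}")
    return (X - means) / sds, means, sds


@dataclass(frozen=True)
class BartlettResult:
    chi2: float
    df: int
    pvalue: float


def bartlett_sphericity(corr, n: int) -> BartlettResult:
    """Bartlett's test that a correlation matrix differs from the identity.

    chi2 = -(n - 1 - (2p + 5) / 6) * ln det(R), df = p(p-1)/2.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("need more observations than variables")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix is singular")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return BartlettResult(chi2=float(chi2), df=df, pvalue=float(stats.chi2.sf(chi2, df)))


def kmo(corr) -> float:
    """Kaiser-Meyer-Olkin overall measure of sampling adequacy.

    MSA = sum(r^2) / (sum(r^2) + sum(q^2)) over off-diagonal entries, where
    q are the anti-image partial correlations from the inverse correlation
    matrix.
    """
    R = np.asarray(corr, dtype=float)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("correlation matrix is singular") from err
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    Q = -Rinv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    q2 = (Q[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def smote(minority, k: int, n_synthetic: int, seed) -> np.ndarray:
    """Synthetic minority rows on segments to k-nearest minority neighbours.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` with ``u ~ U(0, 1)`` and
    ``x_nn`` one of the k nearest minority neighbours of a randomly chosen
    minority row, so every synthetic point lies inside the minority convex
    hull.
    """
    X = np.asarray(minority, dtype=float)
    m = X.shape[0]
    if k < 1 or k >= m:
        raise ValueError(f"k = {k} must satisfy 1 <= k < minority count {m}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]
    base = rng.integers(0, m, n_synthetic)
    pickk = rng.integers(0, k, n_synthetic)
    u = rng.uniform(0, 1, n_synthetic)
    neigh = nn[base, pickk]
    return X[base] + u[:, None] * (X[neigh] - X[base])


@dataclass
class BalancedCalibrationSet:
    """One balanced calibration set with row provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # "original" | "smote-synthetic"
    seed: int

    def label_ratio(self) -> float:
        pos = int(self.y.sum())
        return pos / max(len(self.y) - pos, 1)


def balance_calibration_sets(
    X,
    y,
    n_iterations: int = 20,
    seed: int = 0,
    k_neighbours: int = 5,
    undersample_factor: float = 2.0,
) -> list[BalancedCalibrationSet]:
    """Iteratively derive balanced calibration sets (undersample + SMOTE).

    Each iteration independently (a) undersamples the majority class to
    ``undersample_factor`` times the minority count and (b) SMOTE-augments
    the minority up to parity, using a sub-seed derived from the master
    seed, so the sequence of sets is reproducible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    minority_label = classes[np.argmin(counts)]
    min_idx = np.flatnonzero(y == minority_label)
    maj_idx = np.flatnonzero(y != minority_label)
    if len(min_idx) <= k_neighbours:
        raise ValueError(
            f"minority class ({len(min_idx)}) must exceed k_neighbours ({k_neighbours})"
        )
    sets = []
    for it in range(n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10_000 + it]))
        n_keep = min(len(maj_idx), int(round(undersample_factor * len(min_idx))))
        keep_maj = rng.choice(maj_idx, size=n_keep, replace=False)
        n_synth = max(n_keep - len(min_idx), 0)
        X_min = X[min_idx]
        synth = smote(X_min, k_neighbours, n_synth, rng) if n_synth else np.empty((0, X.shape[1]))
        Xb = np.vstack([X[keep_maj], X_min, synth])
        yb = np.concatenate(
            [np.full(n_keep, 1 - minority_label), np.full(len(min_idx) + n_synth, minority_label)]
        )
        prov = np.array(
            ["original"] * (n_keep + len(min_idx)) + ["smote-synthetic"] * n_synth
        )
        sets.append(BalancedCalibrationSet(X=Xb, y=yb, provenance=prov, seed=int(seed)))
    return sets


def _pc1(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading eigenvector and all eigenvalue shares of a correlation matrix."""
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    shares = evals / evals.sum()
    if len(evals) > 1 and abs(evals[0] - evals[1]) < 1e-10:
        warnings.warn("PC1 degenerate: tied leading eigenvalues", stacklevel=3)
    return evecs[:, 0], shares


@dataclass
class IndexModelResults:
    """Fitted (or published) index model: everything needed to score locations."""

    variables: tuple[str, ...]
    loadings: np.ndarray
    orientation: int
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    rescale_min: float | None = None
    rescale_max: float | None = None
    bartlett: BartlettResult | None = None
    kmo_msa: float | None = None
    variance_explained: np.ndarray | None = None
    variant: str = "combined"
    dropped: tuple[str, ...] = ()
    n_iterations: int = 0
    seed: int | None = None
    source: str = "fitted"

    def raw_score(self, profiles: pd.DataFrame) -> np.ndarray:
        if self.means is None or self.sds is None:
            raise ScoringError(
                "model has no standardization parameters; call calibrate() first"
            )
        missing = [v for v in self.variables if v not in profiles.columns]
        if missing:
            raise ScoringError(f"profiles lack model variable(s): {missing}")
        X = profiles[list(self.variables)].to_numpy(dtype=float)
        Z = (X - self.means) / self.sds
        return self.orientation * (Z @ self.loadings)

    def score(self, profiles: pd.DataFrame, return_flags: bool = False):
        """Index scores in [-1, 1]; out-of-calibration values clamp (flagged)."""
        if self.rescale_min is None or self.rescale_max is None:
            raise ScoringError("model has no rescale bounds; call calibrate() first")
        raw = self.raw_score(profiles)
        span = self.rescale_max - self.rescale_min
        scaled = -1.0 + 2.0 * (raw - self.rescale_min) / span
        clamped = (scaled < -1.0) | (scaled > 1.0)
        scaled = np.clip(scaled, -1.0, 1.0)
        return (scaled, clamped) if return_flags else scaled

    def calibrate(self, profiles: pd.DataFrame) -> "IndexModelResults":
        """Set standardization and rescale parameters from a calibration frame.

        Needed before scoring with the published-loadings model, whose
        printed weights come without means/SDs or score range.
        """
        missing = [v for v in self.variables if v not in profiles.columns]
        if missing:
            raise ScoringError(f"calibration frame lacks variable(s): {missing}")
        _, self.means, self.sds = standardize(profiles[list(self.variables)])
        raw = self.raw_score(profiles)
        self.rescale_min, self.rescale_max = float(raw.min()), float(raw.max())
        if self.rescale_min >= self.rescale_max:
            raise ScoringError("degenerate calibration: all raw scores equal")
        return self

    def summary(self) -> str:
        lines = [
            f"Risk index model ({self.variant}, {self.source})",
            "=" * 46,
            f"{'variable':<28}{'loading':>9}",
        ]
        order = np.argsort(-np.abs(self.loadings))
        for i in order:
            lines.append(f"{self.variables[i]:<28}{self.loadings[i]:>9.3f}")
        if self.dropped:
            lines.append(f"dropped (|loading| < threshold): {', '.join(self.dropped)}")
        lines.append(f"orientation: {self.orientation:+d} (high score = deprived / low greenspace)")
        if self.variance_explained is not None:
            shares = ", ".join(f"{s:.1%}" for s in self.variance_explained[:5])
            lines.append(f"variance explained (PC1..): {shares}")
        if self.bartlett is not None:
            lines.append(
                f"Bartlett chi2({self.bartlett.df}) = {self.bartlett.chi2:.1f}, "
                f"p = {self.bartlett.pvalue:.2e}"
            )
        if self.kmo_msa is not None:
            lines.append(f"KMO overall MSA = {self.kmo_msa:.3f}")
        if self.rescale_min is not None:
            lines.append(
                f"raw-score rescale range: [{self.rescale_min:.3f}, {self.rescale_max:.3f}]"
            )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Serialize as a flat key=value text file."""
        rows = [
            f"source={self.source}",
            f"variant={self.variant}",
            f"orientation={self.orientation}",
            f"n_iterations={self.n_iterations}",
            f"seed={self.seed}",
            f"variables={','.join(self.variables)}",
            f"loadings={','.join(repr(float(v)) for v in self.loadings)}",
        ]
        if self.means is not None:
            rows.append(f"means={','.join(repr(float(v)) for v in self.means)}")
            rows.append(f"sds={','.join(repr(float(v)) for v in self.sds)}")
        if self.rescale_min is not None:
            rows.append(f"rescale_min={float(self.rescale_min)!r}")
            rows.append(f"rescale_max={float(self.rescale_max)!r}")
        if self.dropped:
            rows.append(f"dropped={','.join(self.dropped)}")
        if self.kmo_msa is not None:
            rows.append(f"kmo={float(self.kmo_msa)!r}")
        if self.bartlett is not None:
            rows.append(
                f"bartlett={float(self.bartlett.chi2)!r},{self.bartlett.df},"
                f"{float(self.bartlett.pvalue)!r}"
            )
        if self.variance_explained is not None:
            rows.append(f"variance_explained={','.join(repr(float(v)) for v in self.variance_explained)}")
        Path(path).write_text("\n".join(rows) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "IndexModelResults":
        kv = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                key, _, val = line.partition("=")
                kv[key] = val
        res = cls(
            variables=tuple(kv["variables"].split(",")),
            loadings=np.array([float(v) for v in kv["loadings"].split(",")]),
            orientation=int(kv["orientation"]),
            variant=kv.get("variant", "combined"),
            source=kv.get("source", "fitted"),
            n_iterations=int(kv.get("n_iterations", 0)),
            seed=None if kv.get("seed") in (None, "None") else int(kv["seed"]),
            dropped=tuple(kv["dropped"].split(",")) if kv.get("dropped") else (),
        )
        if "means" in kv:
            res.means = np.array([float(v) for v in kv["means"].split(",")])
            res.sds = np.array([float(v) for v in kv["sds"].split(",")])
        if "rescale_min" in kv:
            res.rescale_min = float(kv["rescale_min"])
            res.rescale_max = float(kv["rescale_max"])
        if "kmo" in kv:
            res.kmo_msa = float(kv["kmo"])
        if "bartlett" in kv:
            c, d, p = kv["bartlett"].split(",")
            res.bartlett = BartlettResult(float(c), int(d), float(p))
        if "variance_explained" in kv:
            res.variance_explained = np.array(
                [float(v) for v in kv["variance_explained"].split(",")]
            )
        return res


class DiabetesRiskIndex:
    """Model object: derive the index from exposure profiles and case labels.

    Parameters
    ----------
    profiles : DataFrame with the exposure variables as columns.
    labels : binary outcome per row (used only for class balancing).
    variant : "combined" (default), "ses_only" or "greenspace_only".
    variables : explicit variable subset, overriding the variant list.
    """

    def __init__(self, profiles: pd.DataFrame, labels, variant: str = "combined",
                 variables=None):
        if variant not in VARIANT_VARIABLES:
            raise ValueError(f"unknown variant {variant!r}")
        if variables is None:
            variables = [v for v in VARIANT_VARIABLES[variant] if v in profiles.columns]
        if len(variables) < 2:
            raise ValueError("need at least 2 variables")
        missing = [v for v in variables if v not in profiles.columns]
        if missing:
            raise KeyError(f"profiles lack variable(s): {missing}")
        self.variant = variant
        self.variables = tuple(variables)
        data = profiles[list(variables)]
        if data.isna().any().any():
            raise ValueError("profiles contain missing values; impute or drop first")
        self.profiles = data
        self.labels = np.asarray(labels).astype(int)
        if len(self.labels) != len(data):
            raise ValueError("labels length != profile rows")
        if len(data) < 10 * len(variables):
            warnings.warn(
                f"only {len(data)} rows for {len(variables)} variables "
                "(< 10x rule of thumb)", stacklevel=2,
            )

    def fit(
        self,
        n_iterations: int = 20,
        seed: int = 0,
        drop_threshold: float = 0.05,
        anchor: str = DEFAULT_ANCHOR,
        k_neighbours: int = 5,
        _drop_pass: bool = True,
    ) -> IndexModelResults:
        """Class-balanced PCA fit; returns the scored, oriented results object."""
        X = self.profiles.to_numpy(dtype=float)
        sets = balance_calibration_sets(
            X, self.labels, n_iterations=n_iterations, seed=seed, k_neighbours=k_neighbours
        )
        loadings_iter = []
        shares_iter = []
        for s in sets:
            corr = np.corrcoef(s.X, rowvar=False)
            vec, shares = _pc1(corr)
            if loadings_iter and float(vec @ loadings_iter[0]) < 0:
                vec = -vec  # sign-align to the first iteration
            loadings_iter.append(vec)
            shares_iter.append(shares)
        loadings = np.mean(loadings_iter, axis=0)
        loadings /= np.linalg.norm(loadings)

        dropped: tuple[str, ...] = ()
        if _drop_pass and drop_threshold > 0:
            weak = np.abs(loadings) < drop_threshold
            if weak.any() and (~weak).sum() >= 2:
                dropped = tuple(np.array(self.variables)[weak])
                refit = DiabetesRiskIndex(
                    self.profiles, self.labels, variant=self.variant,
                    variables=[v for v, w in zip(self.variables, weak) if not w],
                )
                res = refit.fit(
                    n_iterations=n_iterations, seed=seed, drop_threshold=drop_threshold,
                    anchor=anchor, k_neighbours=k_neighbours, _drop_pass=False,
                )
                res.dropped = dropped
                return res

        # orient: anchor deprivation variable must push the score up
        orientation = 1
        if anchor in self.variables:
            if loadings[self.variables.index(anchor)] < 0:
                orientation = -1
        else:  # greenspace-only variant: greener must push the score down
            ndvi_cols = [i for i, v in enumerate(self.variables) if v == "ndvi_median"]
            if ndvi_cols and loadings[ndvi_cols[0]] > 0:
                orientation = -1

        _, means, sds = standardize(self.profiles)
        corr_all = np.corrcoef(self.profiles.to_numpy(dtype=float), rowvar=False)
        try:
            diag_bartlett = bartlett_sphericity(corr_all, n=len(self.profiles))
            diag_kmo = kmo(corr_all)
        except np.linalg.LinAlgError:
            # perfectly collinear inputs: PC1 still defined, diagnostics not
            warnings.warn("singular correlation matrix; diagnostics skipped",
                          stacklevel=2)
            diag_bartlett, diag_kmo = None, None
        res = IndexModelResults(
            variables=self.variables,
            loadings=loadings,
            orientation=orientation,
            means=means,
            sds=sds,
            bartlett=diag_bartlett,
            kmo_msa=diag_kmo,
            variance_explained=np.mean(shares_iter, axis=0),
            variant=self.variant,
            dropped=dropped,
            n_iterations=n_iterations,
            seed=seed,
        )
        # rescale bounds from the pooled balanced calibration rows
        pooled = pd.DataFrame(np.vstack([s.X for s in sets]), columns=self.variables)
        raw = res.raw_score(pooled)
        res.rescale_min, res.rescale_max = float(raw.min()), float(raw.max())
        return res


def fit_index(profiles: pd.DataFrame, labels, variant: str = "combined",
              **fit_kwargs) -> IndexModelResults:
    """Functional wrapper: build the model and fit in one call."""
    return DiabetesRiskIndex(profiles, labels, variant=variant).fit(**fit_kwargs)


def index_variant(profiles: pd.DataFrame, labels, variant: str,
                  **fit_kwargs) -> IndexModelResults:
    """Fit the index restricted to one variant's variable subset."""
    return fit_index(profiles, labels, variant=variant, **fit_kwargs)


def published_model() -> IndexModelResults:
    """The original study's printed loadings as a ready-made model.

    The printed weights come without standardization or rescale parameters;
    call :meth:`IndexModelResults.calibrate` with a profile frame before
    scoring. Orientation is -1 because with the printed signs the
    deprivation anchor loads negatively.
    """
    variables = tuple(PUBLISHED_LOADINGS)
    return IndexModelResults(
        variables=variables,
        loadings=np.array([PUBLISHED_LOADINGS[v] for v in variables]),
        orientation=-1,
        variant="combined",
        source="published",
    )
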