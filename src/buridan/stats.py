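"""Group statistics: outlier filtering, PCA, normality-gated ANOVA, Tukey grouping.

The analysis chain mirrors the standard treatment of multi-strain walking
data: flies whose mean distance travelled falls below 50 mm/min are
excluded as outliers; the twelve locomotor parameters are centred, scaled
to unit variance (they carry incommensurable units) and decomposed by PCA;
a Shapiro-Wilk test gates which components can be analysed parametrically;
a two-way fixed-effects ANOVA (strain, replicate, interaction; Type II
sums of squares) is run on one component's scores; and Tukey's HSD over
strains yields a grouping of strains by transitive closure of the
non-significant pairwise contrasts.

The two estimators follow scikit-learn conventions (``fit``, ``transform``,
``get_params``; fitted attributes end in an underscore) and compose with
sklearn pipelines; the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import UsageError
from .io import ID_COLUMNS, METRIC_COLUMNS

__all__ = [
    "filter_outliers",
    "LocomotorPCA",
    "StrainGroupAnalyzer",
    "PCAResult",
    "AnovaReport",
    "run_pca",
    "anova_on_component",
    "grouping_summary",
    "groups_from_nonsignificant",
    "boxplot_data",
]

logger = logging.getLogger(__name__)

MIN_DISTANCE_PER_MIN = 50.0


def filter_outliers(
    table: pd.DataFrame, min_distance_per_min: float = MIN_DISTANCE_PER_MIN
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude flies with mean distance travelled *smaller than* the threshold.

    The rule is strict: a fly at exactly the threshold is kept.  Returns
    ``(kept, excluded)``; exclusions are logged with their values.
    """
    low = table["distance_per_min"] < min_distance_per_min
    excluded = table.loc[low].copy()
    for _, row in excluded.iterrows():
        logger.info(
            "excluding fly %s (%s/%s): distance %.1f mm/min < %.1f mm/min",
            row.get("fly_id", "?"),
            row.get("strain", "?"),
            row.get("replicate", "?"),
            row["distance_per_min"],
            min_distance_per_min,
        )
    return table.loc[~low].copy(), excluded


class LocomotorPCA(BaseEstimator, TransformerMixin):
    """PCA over the twelve locomotor parameters.

    Because the parameters have incommensurable units, columns are centred
    and scaled to unit variance (sample SD, ddof=1) by default, i.e. the
    decomposition is of the correlation matrix; set ``scale=False`` for a
    covariance-matrix PCA sensitivity analysis.  Rows containing NaN are
    dropped with a warning; constant columns cannot be scaled and are
    dropped with a warning.  Component signs are fixed by making the
    largest-magnitude loading of each component positive.

    Attributes (after ``fit``)
    --------------------------
    components_ : (k, p) array, rows orthonormal.
    loadings_ : (p, k) array, ``components_.T``.
    explained_variance_ratio_ : (k,) array, non-increasing.
    feature_names_ : list of the p columns actually used.
    dropped_features_ : constant columns that were removed.
    row_mask_ : boolean mask of the rows kept (NaN-free).
    """

    def __init__(self, n_components: int | None = None, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def _prepare(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            cols = [c for c in METRIC_COLUMNS if c in X.columns]
            if not cols:
                cols = [c for c in X.columns if c not in ID_COLUMNS]
            return X[cols].astype(float)
        return pd.DataFrame(np.asarray(X, dtype=float))

    def fit(self, X, y=None):
        frame = self._prepare(X)
        if len(frame) < 3:
            raise UsageError("PCA needs at least 3 flies")
        mask = ~frame.isna().any(axis=1)
        if not mask.all():
            warnings.warn(
                f"dropping {int((~mask).sum())} fly/flies with undefined metrics before PCA",
                stacklevel=2,
            )
        frame = frame.loc[mask]
        sd = frame.std(ddof=1)
        dropped = [c for c in frame.columns if sd[c] == 0]
        if dropped:
            warnings.warn(f"dropping constant column(s) before PCA: {dropped}", stacklevel=2)
            frame = frame.drop(columns=dropped)
        self.row_mask_ = mask.to_numpy()
        self.feature_names_ = list(frame.columns)
        self.dropped_features_ = dropped
        self.mean_ = frame.mean().to_numpy()
        self.scale_ = (
            frame.std(ddof=1).to_numpy() if self.scale else np.ones(frame.shape[1])
        )
        Z = (frame.to_numpy() - self.mean_) / self.scale_
        k = self.n_components or min(Z.shape[0] - 1, Z.shape[1])
        pca = _SkPCA(n_components=k, svd_solver="full")
        pca.fit(Z)
        comps = pca.components_
        # deterministic sign convention: dominant loading positive
        flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
        self.components_ = comps * flip[:, None]
        self.loadings_ = self.components_.T
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_components_ = self.components_.shape[0]
        self.n_samples_ = Z.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        frame = self._prepare(X)[self.feature_names_]
        Z = (frame.to_numpy() - self.mean_) / self.scale_
        return Z @ self.loadings_

    def scores_frame(self, X) -> pd.DataFrame:
        """Scores as a DataFrame with PC1..PCk columns (NaN rows excluded)."""
        frame = self._prepare(X)
        frame = frame.loc[~frame.isna().any(axis=1)]
        scores = self.transform(frame)
        return pd.DataFrame(
            scores,
            index=frame.index,
            columns=[f"PC{i + 1}" for i in range(self.n_components_)],
        )


@dataclass
class PCAResult:
    """Container mirroring what downstream reporting needs from a fitted PCA."""

    scores: pd.DataFrame  # flies x components, indexed like the input rows kept
    loadings: pd.DataFrame  # metrics x components
    explained_variance_fraction: np.ndarray
    scaling: dict
    model: LocomotorPCA


def run_pca(table: pd.DataFrame, n_components: int | None = None, scale: bool = True) -> PCAResult:
    """Fit :class:`LocomotorPCA` on a metrics table and package the result."""
    model = LocomotorPCA(n_components=n_components, scale=scale).fit(table)
    scores = model.scores_frame(table)
    loadings = pd.DataFrame(
        model.loadings_, index=model.feature_names_, columns=list(scores.columns)
    )
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=model.explained_variance_ratio_,
        scaling={
            "centered": True,
            "unit_variance": scale,
            "dropped_features": model.dropped_features_,
        },
        model=model,
    )


def groups_from_nonsignificant(
    strains: list[str], nonsignificant_pairs: set[frozenset]
) -> dict:
    """Group strains given the set of non-significant pairwise contrasts.

    Groups are connected components of the non-significance graph
    (transitive closure).  Letters come from the maximal cliques of the
    same graph; with a non-transitive significance pattern a strain can
    carry several letters (overlapping groups), which is reported rather
    than forced into a partition.
    """
    graph = nx.Graph()
    graph.add_nodes_from(strains)
    graph.add_edges_from(tuple(p) for p in nonsignificant_pairs)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort()
    cliques = sorted((sorted(c) for c in nx.find_cliques(graph)), key=lambda c: (c[0], len(c)))
    letters: dict[str, str] = {s: "" for s in strains}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for s in clique:
            letters[s] += letter
    group_of = {s: i for i, comp in enumerate(components) for s in comp}
    return {
        "groups": components,
        "group_of": group_of,
        "letters": letters,
        "ambiguous": len(cliques) != len(components),
    }


@dataclass
class AnovaReport:
    """Normality check, factorial ANOVA and Tukey contrasts for one component."""

    component: str
    shapiro_p: dict
    table: pd.DataFrame  # effect, F, p
    tukey: pd.DataFrame  # pairwise strain contrasts with adjusted p
    grouping: dict
    warnings: list = field(default_factory=list)


def _check_cells(strain: pd.Series, replicate: pd.Series) -> None:
    counts = pd.crosstab(strain, replicate)
    for s in counts.index:
        for r in counts.columns:
            if counts.loc[s, r] < 2:
                raise UsageError(
                    f"strain x replicate cell ({s}, {r}) has fewer than 2 flies"
                )


def _anova_and_tukey(
    scores: np.ndarray, strain: pd.Series, replicate: pd.Series, alpha: float
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    data = pd.DataFrame(
        {"score": scores, "strain": strain.to_numpy(), "replicate": replicate.to_numpy()}
    )
    if data["replicate"].nunique() > 1:
        _check_cells(data["strain"], data["replicate"])
        model = ols("score ~ C(strain) * C(replicate)", data=data).fit()
        raw = anova_lm(model, typ=2)
        effects = {
            "C(strain)": "strain",
            "C(replicate)": "replicate",
            "C(strain):C(replicate)": "strain:replicate",
            "Residual": "residual",
        }
    else:
        model = ols("score ~ C(strain)", data=data).fit()
        raw = anova_lm(model, typ=2)
        effects = {"C(strain)": "strain", "Residual": "residual"}
    table = pd.DataFrame(
        {
            "effect": [effects.get(i, i) for i in raw.index],
            "df": raw["df"].to_numpy(),
            "sum_sq": raw["sum_sq"].to_numpy(),
            "F": raw["F"].to_numpy(),
            "p": raw["PR(>F)"].to_numpy(),
        }
    )
    tk = pairwise_tukeyhsd(data["score"], data["strain"], alpha=alpha)
    pairs = pd.DataFrame(
        tk.summary().data[1:],
        columns=[c.strip() for c in tk.summary().data[0]],
    )
    tukey = pd.DataFrame(
        {
            "strain_a": pairs["group1"].astype(str),
            "strain_b": pairs["group2"].astype(str),
            "mean_diff": pairs["meandiff"].astype(float),
            "p_adj": tk.pvalues,
            "reject": tk.reject,
        }
    )
    nonsig = {
        frozenset((a, b))
        for a, b, rej in zip(tukey["strain_a"], tukey["strain_b"], tukey["reject"])
        if not rej
    }
    grouping = groups_from_nonsignificant(sorted(data["strain"].unique()), nonsig)
    return table, tukey, grouping


class StrainGroupAnalyzer(BaseEstimator):
    """Full grouping analysis over a per-fly metrics table.

    ``fit`` expects a DataFrame with the identifier columns (``strain``,
    ``replicate``) and the twelve metric columns.  It fits
    :class:`LocomotorPCA` (replicates pooled), records Shapiro-Wilk
    normality p-values for the first ``n_shapiro_components`` components,
    runs the factorial ANOVA on the chosen component (1-based; the
    conventional choice is component 2, historically the first one that
    passes the normality gate), applies Tukey's HSD over strains and
    derives the strain grouping.

    Analysing a component that fails the normality gate is allowed but
    triggers a prominent warning, recorded in ``warnings_``.
    """

    def __init__(
        self,
        component: int = 2,
        alpha: float = 0.05,
        normality_alpha: float = 0.05,
        scale: bool = True,
        n_shapiro_components: int = 3,
    ):
        self.component = component
        self.alpha = alpha
        self.normality_alpha = normality_alpha
        self.scale = scale
        self.n_shapiro_components = n_shapiro_components

    def fit(self, X: pd.DataFrame, y=None):
        if "strain" not in X.columns or "replicate" not in X.columns:
            raise UsageError("metrics table must carry 'strain' and 'replicate' columns")
        self.warnings_ = []
        self.pca_ = LocomotorPCA(scale=self.scale).fit(X)
        scores = self.pca_.scores_frame(X)
        labels = X.loc[scores.index, ["strain", "replicate"]].astype(str)

        if not 1 <= self.component <= self.pca_.n_components_:
            raise UsageError(
                f"component must lie in 1..{self.pca_.n_components_}, got {self.component}"
            )
        self.scores_ = scores
        self.shapiro_p_ = {}
        for i in range(min(self.n_shapiro_components, self.pca_.n_components_)):
            self.shapiro_p_[f"PC{i + 1}"] = float(sps.shapiro(scores.iloc[:, i]).pvalue)
        label = f"PC{self.component}"
        for comp, p in self.shapiro_p_.items():
            if p < self.normality_alpha:
                self.warnings_.append(f"{comp} fails the Shapiro normality gate (p = {p:.3g})")
        if self.shapiro_p_.get(label, 1.0) < self.normality_alpha:
            msg = (
                f"{label} scores are not normally distributed "
                f"(Shapiro p = {self.shapiro_p_[label]:.3g}); the parametric ANOVA "
                "on this component is questionable"
            )
            self.warnings_.append(msg)
            warnings.warn(msg, stacklevel=2)

        table, tukey, grouping = _anova_and_tukey(
            scores[label].to_numpy(), labels["strain"], labels["replicate"], self.alpha
        )
        self.anova_table_ = table
        self.tukey_ = tukey
        self.grouping_ = grouping
        self.groups_ = grouping["groups"]
        self.letters_ = grouping["letters"]
        self.report_ = AnovaReport(
            component=label,
            shapiro_p=dict(self.shapiro_p_),
            table=table,
            tukey=tukey,
            grouping=grouping,
            warnings=list(self.warnings_),
        )
        return self


def anova_on_component(
    pca: PCAResult,
    table: pd.DataFrame,
    component: int = 2,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> AnovaReport:
    """Factorial ANOVA + Tukey HSD on one principal component's scores.

    Thin wrapper over the same machinery as :class:`StrainGroupAnalyzer`
    for callers that already hold a fitted :class:`PCAResult`.
    """
    scores = pca.scores
    if not 1 <= component <= scores.shape[1]:
        raise UsageError(f"component must lie in 1..{scores.shape[1]}, got {component}")
    labels = table.loc[scores.index, ["strain", "replicate"]].astype(str)
    shapiro_p = {
        f"PC{i + 1}": float(sps.shapiro(scores.iloc[:, i]).pvalue)
        for i in range(min(3, scores.shape[1]))
    }
    label = f"PC{component}"
    notes = [
        f"{comp} fails the Shapiro normality gate (p = {p:.3g})"
        for comp, p in shapiro_p.items()
        if p < normality_alpha
    ]
    if shapiro_p.get(label, 1.0) < normality_alpha:
        warnings.warn(
            f"{label} fails the normality gate; ANOVA on it is questionable", stacklevel=2
        )
    anova, tukey, grouping = _anova_and_tukey(
        scores[label].to_numpy(), labels["strain"], labels["replicate"], alpha
    )
    return AnovaReport(
        component=label,
        shapiro_p=shapiro_p,
        table=anova,
        tukey=tukey,
        grouping=grouping,
        warnings=notes,
    )


def grouping_summary(report: AnovaReport) -> dict:
    """Strain-to-group assignment from a Tukey table (see :func:`groups_from_nonsignificant`)."""
    return report.grouping


def boxplot_data(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    by: str = "strain",
) -> pd.DataFrame:
    """Per-group distribution summaries for boxplot-style figures.

    For each group and metric: median, quartiles, Tukey whiskers (the most
    extreme data within 1.5 IQR of the quartiles) and the 10th/90th
    percentiles, plus n.
    """
    columns = columns or [c for c in METRIC_COLUMNS if c in table.columns]
    rows = []
    for group, sub in table.groupby(by, sort=True):
        for col in columns:
            v = sub[col].dropna().to_numpy()
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            lo = v[v >= q1 - 1.5 * iqr].min()
            hi = v[v <= q3 + 1.5 * iqr].max()
            rows.append(
                {
                    by: group,
                    "metric": col,
                    "n": int(v.size),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_low": lo,
                    "whisker_high": hi,
                    "p10": np.percentile(v, 10),
                    "p90": np.percentile(v, 90),
                }
            )
    return pd.DataFrame(rows)
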