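"""TGx-DDI biomarker classification by nearest shrunken centroids (NSC).

A 64-gene expression biomarker separates DNA-damage-inducing (DDI) from
non-DDI exposures.  Three analyses are run per chemical x concentration
profile of log2 fold changes versus matched vehicle control:

* probability analysis (PA): NSC class posteriors with a 0.90 call threshold,
* principal component analysis (PCA): projection on the training set's first
  principal component with a midpoint decision boundary and a dead band,
* hierarchical clustering (HC): average-linkage Euclidean clustering with the
  training compounds, cut into two clusters, majority vote.

The composite call is DDI if any analysis calls DDI; non-DDI if all three
call non-DDI; otherwise unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

DDI = "DDI"
NON_DDI = "non-DDI"
UNCLASSIFIED = "unclassified"

__all__ = [
    "TrainingSet", "NSCModel", "ClassificationCall",
    "collapse_probes", "condition_log2fc", "train_nsc", "classify_nsc",
    "choose_delta", "pca_call", "hc_call", "composite_call", "chemical_call",
    "classify_conditions",
]


@dataclass
class TrainingSet:
    """Gene x reference-compound log2-ratio matrix with DDI/non-DDI labels."""

    matrix: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.matrix.columns)
        if self.matrix.isna().any().any() or self.labels.isna().any():
            raise ValueError("training set contains missing values or labels")
        classes = set(self.labels)
        if classes != {DDI, NON_DDI}:
            raise ValueError(f"training labels must be exactly {{{DDI}, {NON_DDI}}}, "
                             f"got {sorted(classes)}")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index


@dataclass
class NSCModel:
    """Fitted nearest-shrunken-centroid model.

    ``d_shrunk`` holds the soft-thresholded standardized differences d'_ik;
    genes fully shrunk in both classes no longer contribute to
    classification.
    """

    genes: pd.Index
    classes: list[str]
    overall_centroid: np.ndarray          # x_bar_i
    class_centroids: np.ndarray           # x_bar_ik (genes x classes), unshrunk
    shrunken_centroids: np.ndarray        # x_bar'_ik
    within_class_sd: np.ndarray           # s_i (pooled)
    s0: float
    delta: float
    d_shrunk: np.ndarray
    priors: np.ndarray

    def n_active_genes(self) -> int:
        return int((np.abs(self.d_shrunk).sum(axis=1) > 0).sum())


@dataclass
class ClassificationCall:
    """Three sub-calls and the composite for one chemical x concentration."""

    chemical: str
    concentration: float
    pa_call: str
    pca_call: str
    hc_call: str
    posterior_ddi: float
    overall: str = field(init=False)

    def __post_init__(self) -> None:
        self.overall = composite_call(self.pa_call, self.pca_call, self.hc_call)


def collapse_probes(values: pd.DataFrame, probe_gene_map: pd.Series,
                    required_genes: pd.Index | None = None) -> pd.DataFrame:
    """Average probe-level log2 values into gene-level rows.

    Genes with multiple probes get the arithmetic mean on the log2 scale.
    If ``required_genes`` is given, every one of them must be covered by at
    least one probe; missing genes are a hard error because the biomarker
    model needs its full feature set.
    """
    genes = probe_gene_map.reindex(values.index)
    if genes.isna().any():
        missing = list(values.index[genes.isna()])
        raise ValueError(f"probes without gene mapping: {missing[:5]}")
    collapsed = values.groupby(genes).mean()
    collapsed.index.name = "gene_symbol"
    if required_genes is not None:
        absent = [g for g in required_genes if g not in collapsed.index]
        if absent:
            raise ValueError(f"biomarker genes with no probe: {absent}")
        collapsed = collapsed.loc[list(required_genes)]
    return collapsed


def condition_log2fc(log2_values: pd.DataFrame, metadata: pd.DataFrame,
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-condition mean log2 fold change versus matched vehicle control.

    Conditions are (chemical, concentration > 0) groups; the matched control
    is the same chemical's vehicle (concentration 0) group.  Returns the
    gene x condition profile matrix (columns are ``chem@conc`` labels) and
    the treated replicate count per condition.
    """
    meta = metadata.set_index("sample_id").loc[
        [s for s in log2_values.columns if s in set(metadata["sample_id"])]]
    profiles, nreps = {}, {}
    for chem, sub in meta.groupby("chemical"):
        ctrl = sub.index[sub["is_vehicle"]]
        for conc, grp in sub[~sub["is_vehicle"]].groupby("concentration_uM"):
            if len(ctrl) == 0:
                raise ValueError(f"no matched vehicle control for {chem} at {conc} uM")
            label = f"{chem}@{conc:g}"
            profiles[label] = (log2_values[grp.index].mean(axis=1)
                               - log2_values[ctrl].mean(axis=1))
            nreps[label] = len(grp)
    return pd.DataFrame(profiles), pd.Series(nreps, name="n_replicates")


def train_nsc(training: TrainingSet, delta: float) -> NSCModel:
    """Fit nearest shrunken centroids with shrinkage Delta.

    Standardized difference d_ik = (x_bar_ik - x_bar_i) / (m_k (s_i + s0)),
    soft-thresholded by Delta; shrunken centroid
    x_bar'_ik = x_bar_i + m_k (s_i + s0) d'_ik; s0 is the median of the
    pooled within-class SDs s_i and m_k = sqrt(1/n_k - 1/n).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    x = training.matrix.to_numpy(dtype=float)
    classes = [DDI, NON_DDI]
    n = x.shape[1]
    cent, mks, within_ss, ns = [], [], np.zeros(x.shape[0]), []
    for k in classes:
        idx = (training.labels == k).to_numpy()
        nk = int(idx.sum())
        if nk < 2:
            raise ValueError(f"class {k!r} has fewer than 2 compounds; "
                             "within-class SD undefined")
        xk = x[:, idx]
        cent.append(xk.mean(axis=1))
        within_ss += ((xk - xk.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        mks.append(np.sqrt(1.0 / nk - 1.0 / n))
        ns.append(nk)
    class_centroids = np.column_stack(cent)
    si = np.sqrt(within_ss / (n - len(classes)))
    s0 = float(np.median(si))
    overall = x.mean(axis=1)
    mk = np.asarray(mks)
    d = (class_centroids - overall[:, None]) / (mk[None, :] * (si + s0)[:, None])
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[:, None] + mk[None, :] * (si + s0)[:, None] * d_shrunk
    priors = np.asarray(ns, dtype=float) / n
    return NSCModel(genes=training.genes, classes=classes,
                    overall_centroid=overall, class_centroids=class_centroids,
                    shrunken_centroids=shrunken, within_class_sd=si, s0=s0,
                    delta=delta, d_shrunk=d_shrunk, priors=priors)


def classify_nsc(model: NSCModel, profile: pd.Series | np.ndarray,
                 posterior_threshold: float = 0.90) -> tuple[float, str]:
    """NSC discriminant posteriors and the probability-analysis call.

    delta_k(x) = sum_i (x_i - x_bar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k;
    posterior proportional to exp(-delta_k / 2).  The call is the class
    whose posterior exceeds the threshold, else unclassified.
    """
    x = _as_gene_vector(model.genes, profile)
    if not np.all(np.isfinite(x)):
        raise ValueError("profile contains non-finite values")
    denom = (model.within_class_sd + model.s0) ** 2
    disc = ((x[:, None] - model.shrunken_centroids) ** 2 / denom[:, None]
            ).sum(axis=0) - 2.0 * np.log(model.priors)
    w = np.exp(-(disc - disc.min()) / 2.0)
    post = w / w.sum()
    posterior_ddi = float(post[model.classes.index(DDI)])
    if posterior_ddi > posterior_threshold:
        call = DDI
    elif 1.0 - posterior_ddi > posterior_threshold:
        call = NON_DDI
    else:
        call = UNCLASSIFIED
    return posterior_ddi, call


def _as_gene_vector(genes: pd.Index, profile) -> np.ndarray:
    if isinstance(profile, pd.Series):
        missing = [g for g in genes if g not in profile.index]
        if missing:
            raise ValueError(f"profile missing model genes: {missing[:5]}")
        return profile.reindex(genes).to_numpy(dtype=float)
    x = np.asarray(profile, dtype=float)
    if x.shape[0] != len(genes):
        raise ValueError("profile length does not match model genes")
    return x


def choose_delta(training: TrainingSet,
                 deltas: np.ndarray | None = None,
                 n_folds: int = 7, seed: int = 0) -> float:
    """Pick the shrinkage by stratified cross-validation on the training set.

    Among shrinkage values tying for the lowest CV error, the largest is
    chosen (the most parsimonious gene set), then frozen for all test data.
    """
    if deltas is None:
        deltas = np.linspace(0.0, 4.0, 17)
    rng = np.random.default_rng(seed)
    cols = np.arange(training.matrix.shape[1])
    labels = training.labels.to_numpy()
    folds = np.zeros(len(cols), dtype=int)
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        folds[idx] = np.arange(len(idx)) % n_folds
    errors = np.zeros(len(deltas))
    for f in range(n_folds):
        hold = folds == f
        sub = TrainingSet(training.matrix.iloc[:, ~hold],
                          training.labels[~hold])
        for j, d in enumerate(deltas):
            model = train_nsc(sub, float(d))
            for c in cols[hold]:
                _, call = classify_nsc(model, training.matrix.iloc[:, c],
                                       posterior_threshold=0.5)
                errors[j] += call != labels[c]
    best = errors == errors.min()
    return float(deltas[np.flatnonzero(best)[-1]])


def pca_call(training: TrainingSet, profile,
             epsilon_fraction: float = 0.10) -> str:
    """Call from the projection on the training set's first principal component.

    Loadings are estimated from the (gene-centered) training compounds only;
    the decision boundary is the midpoint between the two classes' mean PC1
    scores, with a dead band of ``epsilon_fraction`` of the class-mean
    separation inside which the profile is unclassified.
    """
    x = training.matrix.to_numpy(dtype=float)
    center = x.mean(axis=1)
    xc = (x - center[:, None]).T              # compounds x genes
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("degenerate training variance; PCA undefined")
    pc1 = vt[0]
    scores = xc @ pc1
    m_ddi = scores[(training.labels == DDI).to_numpy()].mean()
    m_non = scores[(training.labels == NON_DDI).to_numpy()].mean()
    sep = m_ddi - m_non
    if sep == 0:
        raise ValueError("PC1 does not separate the training classes")
    boundary = (m_ddi + m_non) / 2.0
    z = (_as_gene_vector(training.genes, profile) - center) @ pc1
    signed = (z - boundary) * np.sign(sep)
    if abs(z - boundary) <= epsilon_fraction * abs(sep) / 2.0:
        return UNCLASSIFIED
    return DDI if signed > 0 else NON_DDI


def hc_call(training: TrainingSet, profile) -> str:
    """Call from joint hierarchical clustering with the training compounds.

    Average-linkage Euclidean clustering of the training compounds plus the
    test profile, cut into two clusters; the call is the majority class of
    the training compounds sharing the test profile's cluster.  A tie, or a
    test profile clustering alone, is unclassified.
    """
    for cls in (DDI, NON_DDI):
        if (training.labels == cls).sum() < 2:
            raise ValueError(f"need >= 2 training compounds in class {cls!r}")
    x = training.matrix.to_numpy(dtype=float).T
    z = np.vstack([x, _as_gene_vector(training.genes, profile)])
    labels = fcluster(linkage(z, method="average", metric="euclidean"),
                      t=2, criterion="maxclust")
    mine = labels[-1]
    mates = labels[:-1] == mine
    if not mates.any():
        return UNCLASSIFIED
    n_ddi = int(((training.labels == DDI).to_numpy() & mates).sum())
    n_non = int(((training.labels == NON_DDI).to_numpy() & mates).sum())
    if n_ddi > n_non:
        return DDI
    if n_non > n_ddi:
        return NON_DDI
    return UNCLASSIFIED


def composite_call(pa: str, pca: str, hc: str) -> str:
    """Composite rule: any DDI sub-call -> DDI; all non-DDI -> non-DDI."""
    calls = (pa, pca, hc)
    if DDI in calls:
        return DDI
    if all(c == NON_DDI for c in calls):
        return NON_DDI
    return UNCLASSIFIED


def chemical_call(per_concentration: dict[float, str],
                  cytotoxic: set[float] = frozenset()) -> str:
    """Chemical-level call over non-cytotoxic concentrations.

    DDI if any non-cytotoxic concentration calls DDI; non-DDI if all call
    non-DDI; an unclassified concentration without any DDI call propagates
    to an unclassified chemical.
    """
    calls = [c for conc, c in per_concentration.items() if conc not in cytotoxic]
    if not calls:
        return UNCLASSIFIED
    if DDI in calls:
        return DDI
    if all(c == NON_DDI for c in calls):
        return NON_DDI
    return UNCLASSIFIED


def classify_conditions(training: TrainingSet, profiles: pd.DataFrame,
                        delta: float,
                        posterior_threshold: float = 0.90,
                        epsilon_fraction: float = 0.10,
                        ) -> list[ClassificationCall]:
    """Run PA, PCA and HC for every ``chem@conc`` profile column."""
    model = train_nsc(training, delta)
    calls = []
    for label in profiles.columns:
        chem, conc = label.rsplit("@", 1)
        prof = profiles[label]
        post, pa = classify_nsc(model, prof, posterior_threshold)
        calls.append(ClassificationCall(
            chemical=chem, concentration=float(conc),
            pa_call=pa,
            pca_call=pca_call(training, prof, epsilon_fraction),
            hc_call=hc_call(training, prof),
            posterior_ddi=post))
    return calls
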