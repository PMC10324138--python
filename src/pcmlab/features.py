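"""Pair-matrix assembly and preprocessing.

Builds the pair-by-descriptor matrix at the heart of proteochemometric
modeling (ligand descriptors ++ protein descriptors per bioactivity pair) and
applies the preprocessing chain in a fixed order: mean imputation, the
near-zero-variance frequency-ratio filter, the pairwise-correlation filter,
and centering/scaling fit on training rows only. Also provides the stratified
70/30 split and PCA scores for exploratory plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .chem import BioactivityDataset, LigandDescriptorBlock

__all__ = [
    "FeatureMatrix",
    "SplitAssignment",
    "CenterScaler",
    "build_pair_matrix",
    "impute_features",
    "remove_near_zero_variance",
    "remove_highly_correlated",
    "fit_center_scale",
    "stratified_split",
    "pca_scores",
]

PreprocessingState = Literal["raw", "imputed", "filtered", "scaled"]


@dataclass
class FeatureMatrix:
    """Pair-by-descriptor matrix with provenance and preprocessing state.

    Rows are keyed by (compound_id, target_id); each preprocessing operation
    returns a new FeatureMatrix with an advanced ``preprocessing_state`` so a
    stage cannot be applied out of order.
    """

    values: pd.DataFrame  # MultiIndex (compound_id, target_id) x descriptors
    provenance: pd.Series  # per-column tag: ligand-fingerprint | ligand-physchem | protein-zscale
    preprocessing_state: PreprocessingState = "raw"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("row keys must be unique")
        if list(self.provenance.index) != list(self.values.columns):
            raise ValueError("provenance must cover exactly the matrix columns")

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column_counts_by_provenance(self) -> dict[str, int]:
        return self.provenance.value_counts().to_dict()

    def with_columns(self, keep: list[str], state: PreprocessingState) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[keep],
            provenance=self.provenance[keep],
            preprocessing_state=state,
        )

    def to_csv(self, path) -> None:
        out = self.values.reset_index()
        header = pd.DataFrame(
            [["#provenance", ""] + list(self.provenance)], columns=out.columns
        )
        pd.concat([header, out]).to_csv(path, index=False)


@dataclass
class SplitAssignment:
    """Per-row train/test labels from a stratified, seeded split."""

    labels: pd.Series  # index: row keys; values: "train" | "test"
    ratio: float
    bins: np.ndarray  # bin edges used for stratification
    seed: int

    @property
    def train_keys(self) -> list:
        return list(self.labels.index[self.labels == "train"])

    @property
    def test_keys(self) -> list:
        return list(self.labels.index[self.labels == "test"])

    def to_csv(self, path) -> None:
        out = self.labels.rename("label").reset_index()
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_pair_matrix(
    dataset: BioactivityDataset,
    ligand_block: LigandDescriptorBlock,
    protein_block: tuple[pd.DataFrame, pd.Series] | None,
) -> FeatureMatrix:
    """Concatenate ligand and protein descriptors per bioactivity pair.

    Every pair contributes one row: the compound's ligand descriptors followed
    by the target's protein descriptors (all ligand columns precede all
    protein columns). Passing ``protein_block=None`` yields ligand-only
    (QSAR-mode) rows.
    """
    lig = ligand_block.matrix
    missing_c = sorted(set(dataset.pairs["compound_id"]) - set(lig.index))
    if missing_c:
        raise KeyError(f"no ligand descriptors for compounds: {missing_c}")

    lig_rows = lig.loc[dataset.pairs["compound_id"]].to_numpy(float)
    lig_prov = ligand_block.provenance.replace(
        {"fingerprint": "ligand-fingerprint", "physchem": "ligand-physchem"}
    )

    if protein_block is not None:
        prot, prot_prov = protein_block
        missing_t = sorted(set(dataset.pairs["target_id"]) - set(prot.index))
        if missing_t:
            raise KeyError(f"no protein descriptors for targets: {missing_t}")
        prot_rows = prot.loc[dataset.pairs["target_id"]].to_numpy(float)
        data = np.hstack([lig_rows, prot_rows])
        columns = list(lig.columns) + list(prot.columns)
        provenance = pd.concat([lig_prov, prot_prov])
    else:
        data = lig_rows
        columns = list(lig.columns)
        provenance = lig_prov

    index = pd.MultiIndex.from_frame(
        dataset.pairs[["compound_id", "target_id"]]
    )
    values = pd.DataFrame(data, index=index, columns=columns)
    return FeatureMatrix(values=values, provenance=provenance, preprocessing_state="raw")


# ---------------------------------------------------------------------------
# preprocessing chain
# ---------------------------------------------------------------------------

def impute_features(matrix: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Replace NA/Inf entries by the column mean over finite entries.

    A column with no finite entry is filled with 0 and reported. Returns the
    imputed matrix and the list of all-NA columns.
    """
    if matrix.preprocessing_state != "raw":
        raise ValueError("impute_features expects a raw matrix")
    values = matrix.values.replace([np.inf, -np.inf], np.nan)
    all_na = [c for c in values.columns if values[c].isna().all()]
    means = values.mean()  # skips NaN
    filled = values.fillna(means)
    if all_na:
        filled[all_na] = 0.0
    return (
        FeatureMatrix(filled, matrix.provenance, preprocessing_state="imputed"),
        all_na,
    )


def _freq_ratio(column: np.ndarray) -> float:
    """caret-style frequency ratio: count of mode / count of runner-up mode."""
    _, counts = np.unique(column, return_counts=True)
    if len(counts) == 1:
        return np.inf
    counts = np.sort(counts)[::-1]
    return counts[0] / counts[1]


def remove_near_zero_variance(
    matrix: FeatureMatrix, freq_ratio_cut: float = 30.0
) -> tuple[FeatureMatrix, list[str]]:
    """Drop zero-variance columns and those dominated by a single value.

    A column is removed when the ratio (count of its most frequent value) /
    (count of its second most frequent value) strictly exceeds
    ``freq_ratio_cut`` (default 30, i.e. the 30/1 rule), or when it has a
    single unique value.
    """
    if matrix.preprocessing_state != "imputed":
        raise ValueError("remove_near_zero_variance expects an imputed matrix")
    removed = [
        c
        for c in matrix.values.columns
        if _freq_ratio(matrix.values[c].to_numpy()) > freq_ratio_cut
    ]
    keep = [c for c in matrix.values.columns if c not in set(removed)]
    return matrix.with_columns(keep, state="imputed"), removed


def remove_highly_correlated(
    matrix: FeatureMatrix, cutoff: float = 0.95
) -> tuple[FeatureMatrix, list[str]]:
    """Iteratively break up descriptor pairs with |Pearson r| >= cutoff.

    While any pair of remaining columns correlates at or above the cutoff,
    the most correlated pair is located and the member with the larger mean
    absolute correlation to all other remaining columns is removed. Removal
    order is returned for auditability; the output is guaranteed to contain
    no pair at or above the cutoff.
    """
    if matrix.preprocessing_state != "imputed":
        raise ValueError("remove_highly_correlated expects an imputed, NZV-filtered matrix")
    values = matrix.values
    cols = list(values.columns)
    corr = np.corrcoef(values.to_numpy(float), rowvar=False)
    corr = np.atleast_2d(corr)
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, 0.0)

    alive = np.ones(len(cols), dtype=bool)
    removed: list[str] = []
    while True:
        sub = np.where(alive)[0]
        if len(sub) < 2:
            break
        block = abs_corr[np.ix_(sub, sub)]
        i_flat = int(np.argmax(block))
        i, j = divmod(i_flat, len(sub))
        if block[i, j] < cutoff:
            break
        a, b = sub[i], sub[j]
        # mean |r| to all OTHER remaining columns decides which to drop
        mean_a = abs_corr[a, alive].sum() / max(alive.sum() - 1, 1)
        mean_b = abs_corr[b, alive].sum() / max(alive.sum() - 1, 1)
        drop = a if mean_a >= mean_b else b
        alive[drop] = False
        removed.append(cols[drop])

    keep = [c for c, k in zip(cols, alive) if k]
    return matrix.with_columns(keep, state="filtered"), removed


@dataclass
class CenterScaler:
    """Column-wise center/scale transform fit on training rows only."""

    means: pd.Series
    sds: pd.Series  # sample SD (n-1 denominator)

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if list(matrix.values.columns) != list(self.means.index):
            raise ValueError("column mismatch between scaler and matrix")
        scaled = (matrix.values - self.means) / self.sds
        return FeatureMatrix(scaled, matrix.provenance, preprocessing_state="scaled")


def fit_center_scale(matrix: FeatureMatrix, train_keys: list) -> CenterScaler:
    """Estimate per-column mean and sample SD on the training rows.

    A zero-SD training column raises: such columns should have been removed
    by the near-zero-variance filter.
    """
    if matrix.preprocessing_state != "filtered":
        raise ValueError("fit_center_scale expects a filtered matrix")
    train = matrix.values.loc[train_keys]
    means = train.mean()
    sds = train.std(ddof=1)
    zero = list(sds.index[sds == 0])
    if zero:
        raise ValueError(f"zero-SD training columns (should be filtered): {zero}")
    return CenterScaler(means=means, sds=sds)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def stratified_split(
    y: pd.Series,
    ratio: float = 0.7,
    n_bins: int = 4,
    seed: int = 0,
) -> SplitAssignment:
    """Stratified train/test split on response quantile bins.

    Rows are binned by ``n_bins`` quantiles of the response; within each bin a
    seeded random subset goes to training. The global training size is forced
    to ``round(ratio * n)`` by largest-remainder apportionment of the per-bin
    quotas, so every bin's train fraction is within one row of ``ratio``.
    """
    n = len(y)
    if y.nunique() < n_bins:
        raise ValueError(f"need at least {n_bins} distinct response values")
    values = y.to_numpy(float)
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    # interior edges define the bins; duplicated edges collapse empty bins
    bin_ids = np.clip(np.searchsorted(edges[1:-1], values, side="right"), 0, n_bins - 1)

    n_train_target = int(np.floor(ratio * n + 0.5))
    bins_present = np.unique(bin_ids)
    sizes = {b: int((bin_ids == b).sum()) for b in bins_present}
    quotas = {b: ratio * sizes[b] for b in bins_present}
    base = {b: int(np.floor(quotas[b])) for b in bins_present}
    shortfall = n_train_target - sum(base.values())
    # largest-remainder: hand the leftover rows to the bins that lost the most
    order = sorted(bins_present, key=lambda b: (quotas[b] - base[b]), reverse=True)
    take = dict(base)
    for b in order[: max(shortfall, 0)]:
        take[b] += 1

    rng = np.random.default_rng(seed)
    labels = np.full(n, "test", dtype=object)
    for b in bins_present:
        idx = np.where(bin_ids == b)[0]
        chosen = rng.permutation(idx)[: take[b]]
        labels[chosen] = "train"

    return SplitAssignment(
        labels=pd.Series(labels, index=y.index, name="label"),
        ratio=ratio,
        bins=edges,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(
    matrix: FeatureMatrix | pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scores on the first principal components and explained-variance fractions.

    Operates on an already centered/scaled matrix. Raises when more components
    are requested than the data's rank supports.
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    X = values.to_numpy(float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    out = pd.DataFrame(
        scores, index=values.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return out, pca.explained_variance_ratio_
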