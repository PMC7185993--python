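"""Physicochemical feature encoding and correlation-based feature selection.

Each kept core column contributes five features per sequence: charge,
polarity, hydrophobicity, average accessible surface area and side-chain
volume of the residue at that column.  Gap states are imputed with the
column's non-gap mean for the property.  Feature selection follows the CFS
scheme (Hall 1999): features are discretized with the Fayyad-Irani MDL
criterion, associations are measured by symmetrical uncertainty, and a
best-first forward search maximizes the merit

    M_S = k * mean(r_cf) / sqrt(k + k (k - 1) * mean(r_ff))

within stratified cross-validation folds; the final set is the majority
vote across folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .alignment import AMINO_ACIDS, GAP, AlignedSequenceSet

#: The six donor-sugar classes, in fixed order.  "Others" merges the rare
#: donors (Ara, Fuc, GalF, GlcA, ManNAc, Rham, Xyl).
DONOR_CLASSES = ("Gal", "GalNAc", "Glc", "GlcNAc", "Man", "Others")

PROPERTY_NAMES = ("charge", "polarity", "hydrophobicity", "asa", "volume")

# Default scales: net charge at pH 7; Grantham (1974) polarity;
# Kyte-Doolittle hydrophobicity; average accessible surface area (A^2);
# side-chain van der Waals volume (A^3).  Shipped as an editable table.
_DEFAULT_SCALES = {
    #          charge polarity hydroph   asa  volume
    "A": (0.0,  8.1,  1.8, 115.0,  67.0),
    "C": (0.0,  5.5,  2.5, 135.0,  86.0),
    "D": (-1.0, 13.0, -3.5, 150.0,  91.0),
    "E": (-1.0, 12.3, -3.5, 190.0, 109.0),
    "F": (0.0,  5.2,  2.8, 210.0, 135.0),
    "G": (0.0,  9.0, -0.4,  75.0,  48.0),
    "H": (0.1, 10.4, -3.2, 195.0, 118.0),
    "I": (0.0,  5.2,  4.5, 175.0, 124.0),
    "K": (1.0, 11.3, -3.9, 200.0, 135.0),
    "L": (0.0,  4.9,  3.8, 170.0, 124.0),
    "M": (0.0,  5.7,  1.9, 185.0, 124.0),
    "N": (0.0, 11.6, -3.5, 160.0,  96.0),
    "P": (0.0,  8.0, -1.6, 145.0,  90.0),
    "Q": (0.0, 10.5, -3.5, 180.0, 114.0),
    "R": (1.0, 10.5, -4.5, 225.0, 148.0),
    "S": (0.0,  9.2, -0.8, 115.0,  73.0),
    "T": (0.0,  8.6, -0.7, 140.0,  93.0),
    "V": (0.0,  5.9,  4.2, 155.0, 105.0),
    "W": (0.0,  5.4, -0.9, 255.0, 163.0),
    "Y": (0.0,  6.2, -1.3, 230.0, 141.0),
}


@dataclass
class PropertyTable:
    """Per-residue values for the five amino-acid properties."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.table.index)
        if missing:
            raise ValueError(f"property table lacks residues: {sorted(missing)}")
        if list(self.table.columns) != list(PROPERTY_NAMES):
            raise ValueError(f"property table must have columns {PROPERTY_NAMES}")
        if not np.isfinite(self.table.to_numpy()).all():
            raise ValueError("property table contains non-finite values")

    @classmethod
    def default(cls) -> "PropertyTable":
        df = pd.DataFrame.from_dict(
            _DEFAULT_SCALES, orient="index", columns=list(PROPERTY_NAMES)
        ).loc[list(AMINO_ACIDS)]
        return cls(df)

    def value(self, residue: str, prop: str) -> float:
        try:
            return float(self.table.at[residue, prop])
        except KeyError:
            raise KeyError(f"residue {residue!r} absent from property table")

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("residue").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyTable":
        return cls(pd.read_csv(path, sep="\t", index_col="residue"))

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256(
            self.table.round(6).to_csv().encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class FeatureDescriptor:
    """Traces a numeric feature back to a core column and a property."""

    column_id: int
    property: str

    def __str__(self) -> str:
        return f"c{self.column_id}:{self.property}"


@dataclass
class FeatureMatrix:
    """(sequence x feature) numeric matrix with descriptor bookkeeping."""

    values: np.ndarray
    descriptors: list[FeatureDescriptor]
    sequence_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sequence_ids), len(self.descriptors)):
            raise ValueError("feature matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.labels is not None and len(self.labels) != len(self.sequence_ids):
            raise ValueError("label vector length mismatch")

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    def subset(self, descriptors: Sequence[FeatureDescriptor]) -> "FeatureMatrix":
        index = {d: i for i, d in enumerate(self.descriptors)}
        missing = [d for d in descriptors if d not in index]
        if missing:
            raise KeyError(f"descriptors not in matrix: {[str(d) for d in missing]}")
        cols = [index[d] for d in descriptors]
        return FeatureMatrix(
            self.values[:, cols], list(descriptors), self.sequence_ids, self.labels
        )

    def to_tsv(self, path: str | Path) -> None:
        """Two-line header: column ids, then property names."""
        with open(path, "w") as fh:
            fh.write("column_id\t" + "\t".join(str(d.column_id) for d in self.descriptors) + "\n")
            fh.write("property\t" + "\t".join(d.property for d in self.descriptors) + "\n")
            for sid, row in zip(self.sequence_ids, self.values):
                fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, labels: dict[str, str] | None = None) -> "FeatureMatrix":
        with open(path) as fh:
            cols = fh.readline().rstrip("\n").split("\t")[1:]
            props = fh.readline().rstrip("\n").split("\t")[1:]
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        descriptors = [FeatureDescriptor(int(c), p) for c, p in zip(cols, props)]
        lab = [labels[i] for i in ids] if labels else None
        return cls(np.array(rows), descriptors, ids, lab)


def encode_properties(
    aln: AlignedSequenceSet,
    table: PropertyTable | None = None,
    kept_columns: Sequence[int] | None = None,
    labels: dict[str, str] | None = None,
) -> FeatureMatrix:
    """Encode each (sequence, kept column) pair as five property values.

    ``kept_columns`` are original 1-based column ids (typically the output
    of the >15%-gap filter); descriptors retain those ids.  Gap states are
    imputed with the column's non-gap mean for the property; an all-gap
    column falls back to the table's mean over the 20 residues.
    """
    if table is None:
        table = PropertyTable.default()
    if kept_columns is None:
        kept_columns = aln.column_ids
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    scale = table.table.loc[list(AMINO_ACIDS)].to_numpy()  # (20, 5)
    n_seq = len(aln)
    values = np.empty((n_seq, len(kept_columns) * 5))
    descriptors: list[FeatureDescriptor] = []
    for c_out, cid in enumerate(kept_columns):
        col = aln.column(cid)
        res_idx = np.array([aa_index.get(ch, -1) for ch in col])
        gap_mask = res_idx < 0
        for p_out, prop in enumerate(PROPERTY_NAMES):
            vec = np.where(gap_mask, np.nan, scale[np.clip(res_idx, 0, 19), p_out])
            if gap_mask.any():
                fill = np.nanmean(vec) if not gap_mask.all() else scale[:, p_out].mean()
                vec = np.where(gap_mask, fill, vec)
            values[:, c_out * 5 + p_out] = vec
            descriptors.append(FeatureDescriptor(int(cid), prop))
    return FeatureMatrix(
        values,
        descriptors,
        aln.ids,
        [labels[i] for i in aln.ids] if labels else None,
    )


# ---------------------------------------------------------------------------
# MDL discretization and symmetrical uncertainty


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=-1)


def mdl_discretize(x: np.ndarray, y: np.ndarray, n_classes: int) -> np.ndarray:
    """Fayyad-Irani entropy discretization with the MDL stopping criterion.

    Returns integer bin indices; a feature where no cut is accepted
    collapses to a single bin (carrying no class information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = len(xs)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    prefix = np.vstack([np.zeros(n_classes), np.cumsum(onehot, axis=0)])
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        N = hi - lo
        if N < 2:
            return
        counts = prefix[hi] - prefix[lo]
        s_ent = float(_entropy_rows(counts))
        valid = np.nonzero(xs[lo + 1 : hi] > xs[lo : hi - 1])[0] + lo + 1
        if valid.size == 0:
            return
        left = prefix[valid] - prefix[lo]
        right = counts - left
        n1 = (valid - lo).astype(float)
        n2 = N - n1
        e1, e2 = _entropy_rows(left), _entropy_rows(right)
        weighted = (n1 * e1 + n2 * e2) / N
        b = int(np.argmin(weighted))
        gain = s_ent - weighted[b]
        k = int((counts > 0).sum())
        k1 = int((left[b] > 0).sum())
        k2 = int((right[b] > 0).sum())
        delta = math.log2(3.0**k - 2.0) - (k * s_ent - k1 * e1[b] - k2 * e2[b])
        if gain > (math.log2(N - 1) + delta) / N:
            cut = valid[b]
            cuts.append(0.5 * (xs[cut - 1] + xs[cut]))
            recurse(lo, cut)
            recurse(cut, hi)

    recurse(0, n)
    return np.digitize(x, np.sort(cuts)) if cuts else np.zeros(n, dtype=int)


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """SU(A, B) = 2 * I(A; B) / (H(A) + H(B)); 0 when either is constant."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).astype(float)
    ha = float(_entropy_rows(joint.reshape(na, nb).sum(axis=1))[()])
    hb = float(_entropy_rows(joint.reshape(na, nb).sum(axis=0))[()])
    hab = float(_entropy_rows(joint)[()])
    denom = ha + hb
    if denom <= 0:
        return 0.0
    return max(0.0, 2.0 * (ha + hb - hab) / denom)


# ---------------------------------------------------------------------------
# CFS merit and search


def cfs_merit(
    feature_subset: Sequence[int],
    feature_class_corr: np.ndarray,
    feature_feature_corr: np.ndarray | Callable[[int, int], float],
) -> float:
    """Hall's CFS merit of a feature subset.

    ``M_S = k * mean(r_cf) / sqrt(k + k (k - 1) * mean(r_ff))``; the empty
    subset scores 0 and a singleton scores its own feature-class
    association.
    """
    subset = list(feature_subset)
    k = len(subset)
    if k == 0:
        return 0.0
    r_cf = float(np.mean([feature_class_corr[i] for i in subset]))
    if k == 1:
        return r_cf
    if callable(feature_feature_corr):
        pairs = [
            feature_feature_corr(subset[i], subset[j])
            for i in range(k)
            for j in range(i + 1, k)
        ]
        r_ff = float(np.mean(pairs))
    else:
        sub = np.ix_(subset, subset)
        m = feature_feature_corr[sub]
        r_ff = float((m.sum() - np.trace(m)) / (k * (k - 1)))
    denom = math.sqrt(k + k * (k - 1) * r_ff)
    return k * r_cf / denom if denom > 0 else 0.0


def _cfs_search(
    disc: np.ndarray,
    y: np.ndarray,
    max_stale: int = 5,
    improvement: float = 1e-5,
) -> list[int]:
    """Best-first forward CFS search on discretized features.

    The search extends a single forward path, at each step adding the
    feature that maximizes the merit of the grown subset; it tolerates up
    to ``max_stale`` consecutive additions that fail to improve the best
    merit by more than ``improvement`` and returns the best subset seen.
    """
    n, f = disc.shape
    r_cf = np.array([symmetrical_uncertainty(disc[:, i], y) for i in range(f)])
    su_cache: dict[tuple[int, int], float] = {}

    def su(i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in su_cache:
            su_cache[key] = symmetrical_uncertainty(disc[:, key[0]], disc[:, key[1]])
        return su_cache[key]

    selected: list[int] = []
    sum_rff = np.zeros(f)  # SU sums between each candidate and the selected set
    pair_sum_selected = 0.0  # SU sum over pairs within the selected set
    sel_rcf_sum = 0.0
    best_subset: list[int] = []
    best_merit = 0.0
    stale = 0
    remaining = set(range(f))
    while remaining and stale < max_stale:
        k = len(selected) + 1
        cand = np.fromiter(remaining, dtype=int)
        mean_rcf = (r_cf[cand] + sel_rcf_sum) / k
        if selected:
            n_pairs = k * (k - 1) / 2.0
            mean_rff = (sum_rff[cand] + pair_sum_selected) / n_pairs
            denom = np.sqrt(k + k * (k - 1) * mean_rff)
        else:
            denom = math.sqrt(k)
        merits = k * mean_rcf / denom
        b = int(np.argmax(merits))
        chosen = int(cand[b])
        merit = float(merits[b])
        pair_sum_selected += sum_rff[chosen]
        sel_rcf_sum += r_cf[chosen]
        selected.append(chosen)
        remaining.discard(chosen)
        for other in remaining:
            sum_rff[other] += su(chosen, other)
        if merit > best_merit + improvement:
            best_merit = merit
            best_subset = list(selected)
            stale = 0
        else:
            stale += 1
    return sorted(best_subset)


@dataclass
class CfsSelection:
    """Outcome of CFS with per-fold selection and majority aggregation."""

    selected: list[FeatureDescriptor]
    selected_indices: list[int]
    per_fold: list[list[int]]
    votes: np.ndarray
    min_votes: int


def cfs_select(
    X: FeatureMatrix,
    y: Sequence[str] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    min_votes: int | None = None,
    max_stale: int = 5,
) -> CfsSelection:
    """CFS within stratified CV folds, aggregated by majority vote.

    The search runs independently on each fold's training portion; a
    feature enters the final set when selected in at least ``min_votes``
    folds (default: a strict majority, 3 of 5).  Deterministic under
    ``seed``.
    """
    labels = list(y) if y is not None else X.labels
    if labels is None:
        raise ValueError("labels are required for feature selection")
    classes, y_int = np.unique(labels, return_inverse=True)
    counts = np.bincount(y_int)
    if counts.min() < n_folds:
        small = classes[np.argmin(counts)]
        raise ValueError(
            f"class {small!r} has {counts.min()} members, fewer than {n_folds} folds; "
            "reduce n_folds or merge rare classes"
        )
    if min_votes is None:
        min_votes = n_folds // 2 + 1
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    n_classes = len(classes)
    per_fold: list[list[int]] = []
    votes = np.zeros(X.n_features, dtype=int)
    for train_idx, _ in skf.split(X.values, y_int):
        yt = y_int[train_idx]
        disc = np.column_stack(
            [mdl_discretize(X.values[train_idx, i], yt, n_classes) for i in range(X.n_features)]
        )
        chosen = _cfs_search(disc, yt, max_stale=max_stale)
        per_fold.append(chosen)
        votes[chosen] += 1
    idx = [i for i in range(X.n_features) if votes[i] >= min_votes]
    return CfsSelection(
        selected=[X.descriptors[i] for i in idx],
        selected_indices=idx,
        per_fold=per_fold,
        votes=votes,
        min_votes=min_votes,
    )
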