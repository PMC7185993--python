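"""Per-column conservation and family-characteristic pattern scoring.

Conservation follows the Jensen-Shannon divergence scheme of Capra & Singh
(2007): a column's residue distribution is compared with a background
distribution and the divergence is down-weighted by the column's gap
fraction, so ``score = (1 - gap_fraction) * JSD(p_column, background)`` with
logs base 2 (bounded by 1 at the default mixing weight 0.5).

Family-characteristic positions are scored with a foreground/background
pattern contrast: for a given foreground subset of sequences and a column,
the residue set most enriched in the foreground is found and assessed with a
hypergeometric tail p-value plus a pseudocounted log-odds.  This is a
frequentist stand-in for Bayesian pattern-partitioning approaches that
identify column-wise conservation patterns distinguishing protein
sub-families; per-family p-values are Benjamini-Hochberg adjusted across
columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import AMINO_ACIDS, GAP, AlignedSequenceSet

#: Background amino-acid frequencies implied by the BLOSUM62 matrix
#: (order ACDEFGHIKLMNPQRSTVWY), renormalized to sum to one.
_BLOSUM62_RAW = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}
BLOSUM62_BACKGROUND = np.array([_BLOSUM62_RAW[a] for a in AMINO_ACIDS])
BLOSUM62_BACKGROUND = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()

UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class ColumnDistribution:
    """Residue counts of one alignment column plus a gap count.

    ``probabilities`` spreads ``pseudocount`` over the 20 residues; the gap
    fraction is handled separately as a weight, never as a 21st symbol.
    """

    counts: np.ndarray  # length 20
    gap_count: int = 0
    pseudocount: float = 0.5

    @classmethod
    def from_column(cls, column: str, pseudocount: float = 0.5) -> "ColumnDistribution":
        counts = np.zeros(20)
        gaps = 0
        for ch in column:
            if ch == GAP:
                gaps += 1
            else:
                counts[_AA_INDEX[ch]] += 1
        return cls(counts=counts, gap_count=gaps, pseudocount=pseudocount)

    @property
    def n_residues(self) -> int:
        return int(self.counts.sum())

    @property
    def gap_fraction(self) -> float:
        total = self.n_residues + self.gap_count
        return self.gap_count / total if total else 0.0

    @property
    def probabilities(self) -> np.ndarray:
        smoothed = self.counts + self.pseudocount
        return smoothed / smoothed.sum()


@dataclass
class PatternScore:
    """Foreground-enriched residue pattern at one column."""

    column_id: int
    foreground_pattern: frozenset[str]
    log_odds: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")
        if not np.isfinite(self.log_odds):
            raise ValueError("log_odds must be finite")


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray, lam: float = 0.5) -> float:
    """Weighted JSD with logs base 2: ``lam*KL(p||m) + (1-lam)*KL(q||m)``."""
    m = lam * p + (1.0 - lam) * q
    return lam * _kl(p, m) + (1.0 - lam) * _kl(q, m)


def js_conservation(
    aln: AlignedSequenceSet,
    background: np.ndarray | None = None,
    lam: float = 0.5,
    pseudocount: float = 1e-7,
) -> np.ndarray:
    """Gap-weighted Jensen-Shannon conservation score per core column.

    ``score_c = (1 - gap_fraction_c) * JSD(p_c, background)``, where ``p_c``
    is the column's residue distribution over non-gap states (with a tiny
    smoothing pseudocount, matching the reference implementation of the
    method).  Scores lie in [0, 1] at ``lam = 0.5``; a gap-free column whose
    distribution equals the background scores 0.
    """
    if background is None:
        background = BLOSUM62_BACKGROUND
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or np.any(background <= 0):
        raise ValueError("background must be a full-support distribution over 20 residues")
    background = background / background.sum()
    if len(aln) == 0:
        raise ValueError("cannot score an empty alignment")
    scores = np.empty(aln.n_core_columns)
    for cid in aln.column_ids:
        dist = ColumnDistribution.from_column(aln.column(cid), pseudocount=pseudocount)
        if dist.n_residues == 0:
            scores[cid - 1] = 0.0
            continue
        jsd = jensen_shannon_divergence(dist.probabilities, background, lam)
        scores[cid - 1] = (1.0 - dist.gap_fraction) * jsd
    return scores


def conserved_positions(
    scores: np.ndarray,
    k: int | None = None,
    threshold: float | None = None,
) -> list[tuple[int, float]]:
    """Top-scoring columns, as (1-based column id, score) pairs.

    Either the top ``k`` columns or all columns with score above
    ``threshold``.  Ordering is deterministic: score descending, column id
    ascending on ties.
    """
    if (k is None) == (threshold is None):
        raise ValueError("provide exactly one of k or threshold")
    n = len(scores)
    order = sorted(range(n), key=lambda i: (-scores[i], i))
    ranked = [(i + 1, float(scores[i])) for i in order]
    if k is not None:
        if not 0 <= k <= n:
            raise ValueError(f"k must be in [0, {n}]")
        return ranked[:k]
    return [(cid, s) for cid, s in ranked if s > threshold]


def _prefix_min_p(
    fg_counts: np.ndarray, bg_counts: np.ndarray, pseudocount: float
) -> tuple[float, np.ndarray]:
    """Best (minimum) hypergeometric tail over ratio-ordered residue prefixes.

    Returns the minimal tail probability and the residue indices of the
    minimizing prefix.
    """
    n_fg, n_bg = fg_counts.sum(), bg_counts.sum()
    fg_freq = (fg_counts + pseudocount) / (n_fg + 20 * pseudocount)
    bg_freq = (bg_counts + pseudocount) / (n_bg + 20 * pseudocount)
    order = np.argsort(-(fg_freq / bg_freq), kind="stable")
    k = np.cumsum(fg_counts[order])[:-1]
    K = np.cumsum(fg_counts[order] + bg_counts[order])[:-1]
    total = int(n_fg + n_bg)
    p = stats.hypergeom.sf(k - 1, total, K, int(n_fg))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    best = int(np.argmin(p))
    return float(p[best]), order[: best + 1]


def pattern_contrast(
    aln: AlignedSequenceSet,
    foreground_ids: Sequence[str] | set[str],
    column: int,
    pseudocount: float = 0.5,
    n_permutations: int = 0,
    seed: int = 0,
) -> PatternScore:
    """Score the residue set most enriched in a foreground subset at a column.

    Candidate patterns are the nested prefixes of residues sorted by
    foreground/background frequency ratio; the reported pattern minimizes
    the hypergeometric tail probability of observing at least as many
    foreground sequences carrying a pattern residue.  ``log_odds`` is the
    base-2 pseudocounted ratio of foreground to background pattern
    frequency.  Gap states are excluded from both populations.

    With the default ``n_permutations = 0`` the reported ``p_value`` is the
    *nominal* tail of the selected pattern: exact for a fixed pattern, and
    the right score for ranking columns, but anti-conservative as a test
    because the pattern is chosen on the same data.  With
    ``n_permutations > 0`` the p-value is instead calibrated by permuting
    the foreground labels within the column (``(1 + #{perm <= obs}) /
    (n + 1)``), which makes it super-uniform under the null.
    """
    fg_ids = set(foreground_ids)
    if not fg_ids or fg_ids >= set(aln.ids):
        raise ValueError("foreground must be a nonempty proper subset of the records")
    col = aln.column(column)
    fg_counts = np.zeros(20)
    bg_counts = np.zeros(20)
    residue_idx: list[int] = []
    is_fg: list[bool] = []
    for rec, ch in zip(aln.records, col):
        if ch == GAP:
            continue
        i = _AA_INDEX[ch]
        residue_idx.append(i)
        is_fg.append(rec.id in fg_ids)
        (fg_counts if rec.id in fg_ids else bg_counts)[i] += 1
    n_fg, n_bg = int(fg_counts.sum()), int(bg_counts.sum())
    if n_fg == 0 or n_bg == 0:
        raise ValueError(f"column {column}: empty foreground or background after gap removal")

    p_obs, prefix = _prefix_min_p(fg_counts, bg_counts, pseudocount)
    pattern = frozenset(AMINO_ACIDS[i] for i in prefix)
    fg_freq = (fg_counts + pseudocount) / (n_fg + 20 * pseudocount)
    bg_freq = (bg_counts + pseudocount) / (n_bg + 20 * pseudocount)
    log_odds = float(np.log2(fg_freq[prefix].sum() / bg_freq[prefix].sum()))

    p_value = p_obs
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        residues = np.array(residue_idx)
        n_le = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(residues))
            fg_perm = np.bincount(residues[perm[:n_fg]], minlength=20).astype(float)
            bg_perm = np.bincount(residues[perm[n_fg:]], minlength=20).astype(float)
            p_perm, _ = _prefix_min_p(fg_perm, bg_perm, pseudocount)
            n_le += p_perm <= p_obs
        p_value = (1 + n_le) / (n_permutations + 1)

    return PatternScore(
        column_id=column, foreground_pattern=pattern, log_odds=log_odds, p_value=p_value
    )


def family_characteristic_positions(
    aln: AlignedSequenceSet,
    partition: Mapping[str, str] | None = None,
    top_k: int = 10,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Rank columns by foreground-pattern contrast for every family.

    ``partition`` maps record id to family label (defaults to the records'
    own labels).  For each family with at least two members, every column is
    scored with :func:`pattern_contrast` against all other sequences and
    p-values are Benjamini-Hochberg adjusted across columns; the ``top_k``
    columns by adjusted p-value (ties broken by raw p, then column id) are
    returned in a tidy frame ``(family, column_id, pattern, log_odds, p,
    p_adj)``.  Singleton families are skipped with a warning row omitted.
    """
    if partition is None:
        partition = {r.id: r.family_label or "(unlabeled)" for r in aln}
    families: dict[str, list[str]] = {}
    for rid, fam in partition.items():
        families.setdefault(fam, []).append(rid)
    if len(families) < 2:
        raise ValueError("need at least two families")
    rows = []
    for fam in sorted(families):
        members = families[fam]
        if len(members) < 2:
            import warnings

            warnings.warn(f"family {fam!r} has a single member; skipped")
            continue
        scores = [
            pattern_contrast(aln, members, cid, pseudocount=pseudocount)
            for cid in aln.column_ids
        ]
        pvals = np.array([s.p_value for s in scores])
        p_adj = stats.false_discovery_control(pvals, method="bh")
        order = sorted(
            range(len(scores)), key=lambda i: (p_adj[i], pvals[i], scores[i].column_id)
        )
        for i in order[:top_k]:
            s = scores[i]
            rows.append(
                {
                    "family": fam,
                    "column_id": s.column_id,
                    "pattern": "".join(sorted(s.foreground_pattern)),
                    "log_odds": s.log_odds,
                    "p": s.p_value,
                    "p_adj": float(p_adj[i]),
                }
            )
    return pd.DataFrame(rows, columns=["family", "column_id", "pattern", "log_odds", "p", "p_adj"])
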