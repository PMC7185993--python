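"""Synthetic core alignments with known ground truth.

The generator emulates the statistical structure of a GT-A common-core
alignment so that every pipeline stage is testable without real data:

* a fixed number of core columns (231 by default) drawn from a background
  residue distribution (BLOSUM62 marginals, or uniform for analytic checks);
* a set of globally conserved columns (20 by default, mirroring the number
  of core-conserved positions in the published alignment);
* family-specific conserved columns (invariant within one family, background
  elsewhere);
* donor-class-determining columns whose residue composition differs by
  donor class, half of which are flagged as "donor-site" columns so that
  restricted-feature baselines can be compared against the full model;
* per-column gap rates spanning the 15% filter threshold, and hypervariable
  inserts at three anchor columns (the HV2 anchor carrying an insert longer
  than 28 residues in one family);
* a global substitution-noise rate epsilon: every drawn residue is replaced
  by a uniformly random residue with probability epsilon.

Everything is reproducible from the mandatory seed, and the planted
structure is returned (and serializable) as a :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .alignment import (
    AMINO_ACIDS,
    GAP,
    AlignedSequenceSet,
    CoreAnnotation,
    SequenceRecord,
)
from .conservation import BLOSUM62_BACKGROUND, UNIFORM_BACKGROUND
from .features import DONOR_CLASSES
from .phylo import PhyloTree, TreeNode

_AA = np.array(list(AMINO_ACIDS))

#: Default HV anchor columns (1-based): HV1 after the beta3 strand, HV2
#: between beta6 and beta7, HV3 on the C-terminal tail.
DEFAULT_HV_ANCHORS = {"HV1": 60, "HV2": 120, "HV3": 225}

#: Residues rotated over the class-determining columns.  All are charged or
#: near-charged and mutually distinct across the five property scales, so
#: that every property of a determining column carries class information
#: (class-determining positions in real GT-As are typically charged
#: donor-contacting residues).
_CLASS_RESIDUES = "RDEKH"


def _background(name: str) -> np.ndarray:
    if name == "blosum62":
        return BLOSUM62_BACKGROUND
    if name == "uniform":
        return UNIFORM_BACKGROUND
    raise ValueError(f"unknown background {name!r}")


def _default_global_conserved(n_columns: int, n: int = 20) -> dict[int, str]:
    cols = np.unique(np.linspace(5, n_columns - 5, n).round().astype(int))
    residues = "DGEHWKYPFNRLSTQIVCMA"
    return {int(c): residues[i % 20] for i, c in enumerate(cols)}


def _default_gap_rates(n_columns: int) -> dict[int, float]:
    """Low baseline gap rate with a few columns straddling the 15% cutoff."""
    rates = {c: 0.02 for c in range(1, n_columns + 1)}
    for c in (10, 20):
        rates[c] = 0.30
    for c in (30, 40):
        rates[c] = 0.10
    return rates


@dataclass
class SimulationConfig:
    """Planted structure and sampling parameters for the generators."""

    seed: int
    n_core_columns: int = 231
    # family-structured core alignment
    n_families: int = 3
    seqs_per_family: int = 30
    planted_global_conserved: dict[int, str] | None = None
    planted_family_specific: list[tuple[str, int, str]] | None = None
    insert_spec: dict[int, dict[str, int]] | None = None
    # donor-labelled dataset
    donor_classes: tuple[str, ...] = DONOR_CLASSES
    n_per_class: int = 120
    n_determining_columns: int = 4
    planted_donor_columns: list[tuple[str, int, str]] | None = None
    # shared
    gap_rate: float | dict[int, float] | None = None
    noise: float = 0.05
    background: str = "blosum62"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset (serializable as YAML)."""

    kind: str
    seed: int
    noise: float
    background: str
    labels: dict[str, str]
    global_conserved: dict[int, str] = field(default_factory=dict)
    family_specific: list[tuple[str, int, str]] = field(default_factory=list)
    donor_columns: dict[str, dict[int, str]] = field(default_factory=dict)
    donor_site_columns: dict[str, list[int]] = field(default_factory=dict)
    gap_rates: dict[int, float] = field(default_factory=dict)
    insert_spec: dict[int, dict[str, int]] = field(default_factory=dict)
    tree_newick: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["family_specific"] = [list(t) for t in self.family_specific]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroundTruth":
        data = yaml.safe_load(Path(path).read_text())
        data["family_specific"] = [tuple(t) for t in data.get("family_specific", [])]
        data["donor_columns"] = {
            k: {int(c): r for c, r in v.items()} for k, v in data.get("donor_columns", {}).items()
        }
        data["global_conserved"] = {int(c): r for c, r in data.get("global_conserved", {}).items()}
        data["gap_rates"] = {int(c): float(v) for c, v in data.get("gap_rates", {}).items()}
        data["insert_spec"] = {
            int(a): dict(v) for a, v in data.get("insert_spec", {}).items()
        }
        return cls(**data)


def default_core_annotation(n_columns: int = 231) -> CoreAnnotation:
    """A plausible core annotation with the default HV anchors and motifs."""
    ss = ["loop"] * n_columns
    motif = ["none"] * n_columns
    hv = ["none"] * n_columns
    for start, end, label in [
        (1, 8, "beta"), (12, 24, "alpha"), (28, 34, "beta"), (40, 52, "alpha"),
        (55, 60, "beta"), (64, 75, "alpha"), (80, 86, "beta"), (95, 104, "beta"),
        (110, 120, "beta"), (125, 132, "beta"), (140, 150, "alpha"),
        (160, 170, "alpha"), (180, 192, "alpha"), (200, 206, "beta"), (212, 224, "alpha"),
    ]:
        for c in range(start, min(end, n_columns) + 1):
            ss[c - 1] = label
    for c in (100, 101, 102):
        motif[c - 1] = "DxD"
    for c in (180, 181, 182):
        motif[c - 1] = "xED"
    if n_columns >= 151:
        motif[150] = "G-loop"
    if n_columns >= 207:
        motif[206] = "C-His"
    for c in (30, 45, 90, 155, 210):
        if c <= n_columns:
            motif[c - 1] = "hydrophobic-core"
    for name, col in DEFAULT_HV_ANCHORS.items():
        if col <= n_columns:
            hv[col - 1] = name
    return CoreAnnotation(ss_element=ss, motif_tag=motif, hv_anchor=hv)


def _apply_noise(chars: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    if noise <= 0:
        return chars
    mask = rng.random(chars.shape) < noise
    chars[mask] = _AA[rng.integers(0, 20, size=int(mask.sum()))]
    return chars


def _gap_rate_vector(
    gap_rate: float | Mapping[int, float] | None,
    n_columns: int,
    protected: set[int],
) -> np.ndarray:
    if gap_rate is None:
        rates = _default_gap_rates(n_columns)
    elif isinstance(gap_rate, Mapping):
        rates = {c: 0.0 for c in range(1, n_columns + 1)}
        rates.update(gap_rate)
    else:
        rates = {c: float(gap_rate) for c in range(1, n_columns + 1)}
    vec = np.array([rates.get(c, 0.0) for c in range(1, n_columns + 1)])
    for c in protected:
        vec[c - 1] = 0.0
    return vec


def generate_core_alignment(
    config: SimulationConfig,
) -> tuple[AlignedSequenceSet, GroundTruth]:
    """Family-structured core alignment with planted conserved columns.

    Background columns are drawn i.i.d. from the configured background;
    globally conserved columns carry a fixed residue in every sequence and
    family-specific columns a fixed residue within their family.  Gaps are
    injected per cell at per-column rates (planted columns protected) and
    HV inserts are attached at their anchor columns with per-family lengths.
    """
    rng = np.random.default_rng(config.seed)
    bg = _background(config.background)
    n_cols = config.n_core_columns
    families = [f"F{i + 1}" for i in range(config.n_families)]

    global_cons = (
        dict(config.planted_global_conserved)
        if config.planted_global_conserved is not None
        else _default_global_conserved(n_cols)
    )
    if config.planted_family_specific is not None:
        fam_spec = list(config.planted_family_specific)
    else:
        fam_spec = []
        residues = "YNQK"
        base = 70
        for fi, fam in enumerate(families):
            for j in range(4):
                col = base + fi * 20 + j * 4
                if col in global_cons or col > n_cols:
                    col += 1
                fam_spec.append((fam, col, residues[j % len(residues)]))
    insert_spec = (
        dict(config.insert_spec)
        if config.insert_spec is not None
        else {
            DEFAULT_HV_ANCHORS["HV1"]: {f: 5 for f in families},
            DEFAULT_HV_ANCHORS["HV2"]: {
                f: (32 if i == 0 else 10) for i, f in enumerate(families)
            },
            DEFAULT_HV_ANCHORS["HV3"]: {f: 8 for f in families},
        }
    )
    for fam, col, _ in fam_spec:
        if fam not in families:
            raise ValueError(f"family-specific plant names unknown family {fam!r}")
        if not 1 <= col <= n_cols:
            raise ValueError(f"planted column {col} out of range")
    protected = set(global_cons) | {c for _, c, _ in fam_spec}
    gap_vec = _gap_rate_vector(config.gap_rate, n_cols, protected)

    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for fam in families:
        fam_cols = {c: r for f, c, r in fam_spec if f == fam}
        for s in range(config.seqs_per_family):
            chars = _AA[rng.choice(20, size=n_cols, p=bg)]
            for c, r in global_cons.items():
                chars[c - 1] = r
            for c, r in fam_cols.items():
                chars[c - 1] = r
            chars = _apply_noise(chars, config.noise, rng)
            gap_mask = rng.random(n_cols) < gap_vec
            chars[gap_mask] = GAP
            inserts = {}
            for anchor, by_family in insert_spec.items():
                length = int(by_family.get(fam, 0))
                if length > 0:
                    inserts[int(anchor)] = "".join(
                        _AA[rng.choice(20, size=length, p=bg)]
                    )
            rid = f"{fam}_s{s + 1:03d}"
            records.append(
                SequenceRecord(
                    id=rid, core_states="".join(chars), inserts=inserts, family_label=fam
                )
            )
            labels[rid] = fam
    aln = AlignedSequenceSet(records, n_cols)
    truth = GroundTruth(
        kind="core",
        seed=config.seed,
        noise=config.noise,
        background=config.background,
        labels=labels,
        global_conserved={int(c): r for c, r in global_cons.items()},
        family_specific=[(f, int(c), r) for f, c, r in fam_spec],
        gap_rates={c: float(gap_vec[c - 1]) for c in range(1, n_cols + 1)},
        insert_spec={int(a): dict(v) for a, v in insert_spec.items()},
    )
    return aln, truth


def default_donor_columns(
    config: SimulationConfig,
) -> tuple[dict[str, dict[int, str]], dict[str, list[int]]]:
    """Default class-determining columns and their donor-site subset.

    Each donor class receives ``n_determining_columns`` columns carrying a
    class-characteristic residue (rotated over charged, property-distinct
    residues so that every property of every planted column is
    informative); the first half of each class's columns are flagged as
    "donor-site" columns (the analog of donor-binding residues), leaving
    the rest of the signal off-site.
    """
    if config.planted_donor_columns is not None:
        donor_cols: dict[str, dict[int, str]] = {}
        for cls, col, res in config.planted_donor_columns:
            donor_cols.setdefault(cls, {})[int(col)] = res
    else:
        n_total = len(config.donor_classes) * config.n_determining_columns
        cols = np.unique(
            np.linspace(8, config.n_core_columns - 3, n_total).round().astype(int)
        )
        donor_cols = {}
        for i, cls in enumerate(config.donor_classes):
            chunk = cols[
                i * config.n_determining_columns : (i + 1) * config.n_determining_columns
            ]
            donor_cols[cls] = {
                int(c): _CLASS_RESIDUES[(i + j) % len(_CLASS_RESIDUES)]
                for j, c in enumerate(chunk)
            }
    site = {
        cls: sorted(cols_map)[: max(1, len(cols_map) // 2)]
        for cls, cols_map in donor_cols.items()
    }
    return donor_cols, site


def generate_donor_dataset(
    config: SimulationConfig,
) -> tuple[AlignedSequenceSet, dict[str, str], GroundTruth]:
    """Donor-labelled core alignment with class-determining columns.

    For a sequence of class *c*, each of *c*'s determining columns carries
    the class residue with probability ``1 - noise`` (uniform otherwise);
    all other columns — including other classes' determining columns — are
    background draws, so the planted columns are the only class signal and
    the Bayes-optimal accuracy of the scheme is computable (see
    :func:`bayes_rate`).
    """
    if len(config.donor_classes) < 2:
        raise ValueError("need at least two donor classes")
    rng = np.random.default_rng(config.seed)
    bg = _background(config.background)
    n_cols = config.n_core_columns
    donor_cols, site_cols = default_donor_columns(config)
    protected = {c for cols_map in donor_cols.values() for c in cols_map}
    gap_vec = _gap_rate_vector(config.gap_rate, n_cols, protected)

    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for cls in config.donor_classes:
        own = donor_cols.get(cls, {})
        for s in range(config.n_per_class):
            chars = _AA[rng.choice(20, size=n_cols, p=bg)]
            for c, r in own.items():
                chars[c - 1] = r
            chars = _apply_noise(chars, config.noise, rng)
            gap_mask = rng.random(n_cols) < gap_vec
            chars[gap_mask] = GAP
            rid = f"{cls}_s{s + 1:03d}"
            records.append(
                SequenceRecord(id=rid, core_states="".join(chars), family_label=cls)
            )
            labels[rid] = cls
    aln = AlignedSequenceSet(records, n_cols)
    truth = GroundTruth(
        kind="donor",
        seed=config.seed,
        noise=config.noise,
        background=config.background,
        labels=labels,
        donor_columns={c: dict(m) for c, m in donor_cols.items()},
        donor_site_columns={c: list(v) for c, v in site_cols.items()},
        gap_rates={c: float(gap_vec[c - 1]) for c in range(1, n_cols + 1)},
    )
    return aln, labels, truth


def bayes_rate(
    truth: GroundTruth, n_samples: int = 20000, seed: int = 0
) -> float:
    """Monte-Carlo estimate of the Bayes-optimal accuracy of the scheme.

    Samples class-conditional residues at the planted determining columns
    (equal class priors, the generator's noise model, no gaps) and applies
    the exact posterior argmax.  Only the determining columns enter the
    likelihood: all other columns are identically distributed across
    classes and cancel.
    """
    classes = sorted(truth.donor_columns)
    if not classes:
        raise ValueError("ground truth carries no donor columns")
    bg = _background(truth.background)
    eps = truth.noise
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    all_cols = sorted({c for m in truth.donor_columns.values() for c in m})
    col_pos = {c: i for i, c in enumerate(all_cols)}
    n_cols = len(all_cols)
    n_cls = len(classes)

    # per-class emission matrix over the planted columns: (n_cls, n_cols, 20)
    base = (1.0 - eps) * bg + eps / 20.0
    emission = np.tile(base, (n_cls, n_cols, 1))
    for ci, cls in enumerate(classes):
        for col, res in truth.donor_columns[cls].items():
            row = np.full(20, eps / 20.0)
            row[aa_index[res]] += 1.0 - eps
            emission[ci, col_pos[col]] = row

    rng = np.random.default_rng(seed)
    true_cls = rng.integers(0, n_cls, size=n_samples)
    log_em = np.log(emission)
    correct = 0
    for ci in range(n_cls):
        n_i = int(np.sum(true_cls == ci))
        if n_i == 0:
            continue
        # sample residues column-wise from the class-conditional emissions
        draws = np.empty((n_i, n_cols), dtype=int)
        for j in range(n_cols):
            draws[:, j] = rng.choice(20, size=n_i, p=emission[ci, j])
        loglik = np.zeros((n_i, n_cls))
        for h in range(n_cls):
            loglik[:, h] = log_em[h, np.arange(n_cols), draws].sum(axis=1)
        correct += int(np.sum(np.argmax(loglik, axis=1) == ci))
    return correct / n_samples


# ---------------------------------------------------------------------------
# Tree-structured simulation


def random_phylo_tree(
    n_leaves: int,
    rng: np.random.Generator,
    min_length: float = 0.05,
    max_length: float = 1.0,
) -> PhyloTree:
    """Random binary tree with positive branch lengths (for recovery tests)."""
    if n_leaves < 3:
        raise ValueError("need at least three leaves")

    def L() -> float:
        return float(rng.uniform(min_length, max_length))

    nodes = [TreeNode(label=f"L{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[(nodes[i], L()), (nodes[j], L())])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = TreeNode(children=[(n, L()) for n in nodes])
    return PhyloTree(root=root)


def evolve_along_tree(
    tree: PhyloTree,
    root_sequence: str,
    rate: float = 1.0,
    seed: int = 0,
) -> AlignedSequenceSet:
    """Independent-site 20-state Jukes-Cantor-style evolution along a tree.

    Branch lengths are expected substitutions per site (scaled by
    ``rate``); a site changes with probability
    ``(19/20) * (1 - exp(-20/19 * rate * length))`` and then picks one of
    the 19 other residues uniformly.  Leaves are returned aligned (the
    model has no indels), so pairwise p-distances saturate at 19/20 for
    long branches.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    for ch in root_sequence:
        if ch not in AMINO_ACIDS:
            raise ValueError(f"illegal residue {ch!r} in root sequence")
    rng = np.random.default_rng(seed)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    root = np.array([aa_index[ch] for ch in root_sequence])
    leaves: list[SequenceRecord] = []

    def mutate(seq: np.ndarray, length: float) -> np.ndarray:
        t = rate * max(length, 0.0)
        p_change = (19.0 / 20.0) * (1.0 - np.exp(-20.0 / 19.0 * t))
        out = seq.copy()
        mask = rng.random(seq.shape) < p_change
        if mask.any():
            shift = rng.integers(1, 20, size=int(mask.sum()))
            out[mask] = (out[mask] + shift) % 20
        return out

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            leaves.append(
                SequenceRecord(id=node.label, core_states="".join(_AA[seq]))
            )
            return
        for child, length in node.children:
            walk(child, mutate(seq, length))

    walk(tree.root, root)
    return AlignedSequenceSet(leaves, len(root_sequence))


# ---------------------------------------------------------------------------
# Dataset persistence


def save_dataset(
    aln: AlignedSequenceSet,
    truth: GroundTruth,
    out_dir: str | Path,
    labels: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write alignment (A2M), labels (TSV) and ground truth (YAML)."""
    from .alignment import write_core_alignment

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.a2m.fasta",
        "labels": out / "labels.tsv",
        "ground_truth": out / "ground_truth.yaml",
    }
    write_core_alignment(aln, paths["alignment"])
    lab = labels if labels is not None else truth.labels
    with open(paths["labels"], "w") as fh:
        fh.write("sequence_id\tlabel\n")
        for rid, l in lab.items():
            fh.write(f"{rid}\t{l}\n")
    truth.to_yaml(paths["ground_truth"])
    return paths
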