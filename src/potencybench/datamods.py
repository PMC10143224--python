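"""Activity-class modification procedures and train/test partitioning.

Three interventions probe why simple potency predictors rival machine
learning on medicinal-chemistry data sets:

* **Potency-range balancing** removes the low-micromolar skew by
  down-sampling to (near-)even occupancy of six one-log pIC50 bins,
  yielding half-sized class variants.
* **Nearest-neighbor removal** deletes the structurally most redundant
  half of a class: compounds ranked by their highest Tanimoto similarity
  to any other class member, top fraction removed in a single ranking pass.
* **Analog-series partitioning** assigns whole analog series to either the
  training or the test set, so the two sets share no core structure and
  nearest-neighbor memorization across series boundaries is impossible.

Random reduction and random splits provide the size-matched controls. All
stochastic operations are pure functions of (input, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from ._util import round_half_away
from .chem import fingerprints_for, parse_mol, tanimoto_matrix
from .containers import ActivityClass

logger = logging.getLogger(__name__)

#: pIC50 bin edges: six one-log bins 5-6 ... 10-11; last bin right-closed.
DEFAULT_BIN_EDGES = (5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0)


@dataclass(frozen=True)
class BalanceConfig:
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    target_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        edges = self.bin_edges
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin_edges must be strictly increasing")
        if not 0.0 < self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in (0, 1]")


@dataclass(frozen=True)
class AnalogSeries:
    """Compounds sharing one core structure; always >= 2 members."""

    core: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("an analog series needs at least two members")


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, covering train/test compound-id sets for one trial."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: float
    mode: str  # "random" | "analog_series"
    trial_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")
        if not self.train_ids or not self.test_ids:
            raise ValueError("degenerate split: empty train or test set")


def potency_bin(potency: float, edges: Sequence[float]) -> int:
    """Bin index of a potency; bins right-open except the last (right-closed)."""
    if not edges[0] <= potency <= edges[-1]:
        raise ValueError(f"potency {potency} outside bin support [{edges[0]}, {edges[-1]}]")
    for i in range(len(edges) - 1):
        if potency < edges[i + 1]:
            return i
    return len(edges) - 2


def balance_potency(cls: ActivityClass, config: BalanceConfig | None = None) -> ActivityClass:
    """Down-sample a class to an (approximately) even potency distribution.

    The target size is ``round(target_fraction * |cls|)``. Each bin first
    contributes up to a uniform quota ``floor(target / n_bins)`` of its
    compounds (chosen uniformly at random, seeded); the remaining capacity
    is then distributed one compound at a time, round-robin over the bins
    that still have unselected compounds, until the target size is exact.
    Sparse high-potency bins therefore contribute everything they have
    while the populous low bins are truncated.
    """
    config = config or BalanceConfig()
    if len(cls) == 0:
        raise ValueError("empty class")
    target = round_half_away(config.target_fraction * len(cls))
    if target > len(cls):
        raise ValueError("target size exceeds class size")
    n_bins = len(config.bin_edges) - 1
    rng = np.random.default_rng(config.seed)

    bins: list[list[str]] = [[] for _ in range(n_bins)]
    for r in cls.records:
        bins[potency_bin(r.potency, config.bin_edges)].append(r.compound_id)
    # seeded uniform order within each bin; selection takes prefixes
    shuffled = [list(rng.permutation(b)) if b else [] for b in bins]

    quota = target // n_bins
    take = [min(quota, len(b)) for b in shuffled]
    remaining = target - sum(take)
    while remaining > 0:
        progressed = False
        for i in range(n_bins):
            if remaining == 0:
                break
            if take[i] < len(shuffled[i]):
                take[i] += 1
                remaining -= 1
                progressed = True
        if not progressed:  # unreachable: target <= |cls|
            raise RuntimeError("balancing failed to reach target size")

    selected = {cid for i in range(n_bins) for cid in shuffled[i][: take[i]]}
    return cls.subset(selected, provenance="balanced",
                      lineage=f"{cls.lineage}|balanced(f={config.target_fraction})")


def nearest_neighbor_similarities(cls: ActivityClass) -> dict[str, float]:
    """Each compound's highest Tanimoto similarity to any other class member."""
    if len(cls) < 2:
        raise ValueError("need at least two compounds")
    fps = fingerprints_for([r.structure for r in cls.records])
    sim = tanimoto_matrix(fps)
    np.fill_diagonal(sim, -np.inf)
    nn = sim.max(axis=1)
    return {r.compound_id: float(s) for r, s in zip(cls.records, nn)}


def remove_nearest_neighbors(cls: ActivityClass, fraction: float = 0.5) -> ActivityClass:
    """Remove the top fraction of compounds ranked by nearest-neighbor similarity.

    Similarities are computed once on the original class (single ranking
    pass, no iterative recomputation). Ties in nn-similarity are broken by
    ascending compound_id so the operation is deterministic.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return cls.subset(cls.compound_ids, provenance="nn_removed",
                          lineage=f"{cls.lineage}|nn_removed(f=0)")
    nn = nearest_neighbor_similarities(cls)
    ranked = sorted(nn, key=lambda cid: (-nn[cid], cid))
    n_remove = int(np.floor(fraction * len(cls)))
    removed = set(ranked[:n_remove])
    kept = [cid for cid in cls.compound_ids if cid not in removed]
    return cls.subset(kept, provenance="nn_removed",
                      lineage=f"{cls.lineage}|nn_removed(f={fraction})")


def random_reduce(cls: ActivityClass, fraction: float, seed: int) -> ActivityClass:
    """Uniform random subset of size ``round(fraction * |cls|)`` (seeded)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    size = round_half_away(fraction * len(cls))
    if size == 0:
        raise ValueError("reduction would empty the class")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(cls.compound_ids, size=size, replace=False))
    return cls.subset(chosen, provenance="random_reduced",
                      lineage=f"{cls.lineage}|random_reduced(f={fraction},seed={seed})")


# ---------------------------------------------------------------------------
# analog-series extraction and partitioning


def _candidate_cores(mol: Chem.Mol) -> set[str]:
    """Candidate cores from single cuts at exocyclic single bonds.

    A cut is valid when the larger fragment keeps every ring and at least
    2/3 of the heavy atoms; that fragment (with a [*] attachment mark) is
    the candidate core.
    """
    n_rings = rdMolDescriptors.CalcNumRings(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    cores: set[str] = set()
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        frag = Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True, dummyLabels=[(0, 0)])
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
        if len(pieces) != 2:
            continue
        for piece in pieces:
            heavy = sum(1 for a in piece.GetAtoms() if a.GetAtomicNum() > 0)
            try:
                Chem.SanitizeMol(piece)
            except Exception:
                continue
            if rdMolDescriptors.CalcNumRings(piece) == n_rings and heavy >= (2 * n_heavy) / 3:
                cores.add(Chem.MolToSmiles(piece))
    return cores


def _generic_scaffold(mol: Chem.Mol) -> str | None:
    try:
        scaf = MurckoScaffold.GetScaffoldForMol(mol)
        if scaf is None or scaf.GetNumHeavyAtoms() == 0:
            return None
        return "generic:" + Chem.MolToSmiles(MurckoScaffold.MakeScaffoldGeneric(scaf))
    except Exception:
        return None


def extract_analog_series(cls: ActivityClass) -> list[AnalogSeries]:
    """Partition (a subset of) a class into analog series of >= 2 members.

    Compounds propose candidate cores by systematic single-cut
    fragmentation at exocyclic single bonds (larger fragment keeps all
    rings and >= 2/3 of heavy atoms); compounds with no valid cut fall back
    to their generic Murcko scaffold. Cores are grouped greedily, largest
    unassigned group first (ties by core string), each compound joining at
    most one series; singletons are discarded.
    """
    proposals: dict[str, set[str]] = {}
    for r in cls.records:
        mol = parse_mol(r.structure)
        cores = _candidate_cores(mol)
        if not cores:
            generic = _generic_scaffold(mol)
            cores = {generic} if generic else set()
        for core in cores:
            proposals.setdefault(core, set()).add(r.compound_id)

    assigned: set[str] = set()
    series: list[AnalogSeries] = []
    while True:
        best_core, best_members = None, None
        for core, members in proposals.items():
            free = members - assigned
            if len(free) < 2:
                continue
            if (
                best_members is None
                or len(free) > len(best_members)
                or (len(free) == len(best_members) and core < best_core)
            ):
                best_core, best_members = core, free
        if best_core is None:
            break
        assigned |= best_members
        series.append(AnalogSeries(core=best_core, member_ids=tuple(sorted(best_members))))
    series.sort(key=lambda s: (-len(s.member_ids), s.core))
    return series


def analog_partition(
    series: Sequence[AnalogSeries], ratio: float = 0.8, seed: int = 0, trial_index: int = 0
) -> SplitPlan:
    """Assign whole analog series to train or test (no analog overlap).

    Greedy, overshoot-avoiding: series are shuffled with the seed, then
    each is placed in the test set only while that moves the test compound
    count closer to ``(1 - ratio) * total``; everything else trains. If no
    series fits the target, the smallest series becomes the test set. The
    achieved train fraction is within +-0.05 of ``ratio`` whenever the
    series-size multiset allows it.
    """
    if len(series) < 2:
        raise ValueError("analog partition needs at least two series")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(series)))
    total = sum(len(s.member_ids) for s in series)
    target_test = (1.0 - ratio) * total

    test_idx: list[int] = []
    test_count = 0
    for i in order:
        size = len(series[i].member_ids)
        if test_count >= target_test:
            break
        if abs(test_count + size - target_test) <= abs(test_count - target_test):
            test_idx.append(i)
            test_count += size
    if not test_idx:
        smallest = min(order, key=lambda i: (len(series[i].member_ids), i))
        test_idx = [smallest]
    if len(test_idx) == len(series):  # keep train non-empty
        test_idx = test_idx[:-1]

    test_set = set(test_idx)
    train_ids = tuple(cid for i in range(len(series)) if i not in test_set
                      for cid in series[i].member_ids)
    test_ids = tuple(cid for i in sorted(test_set) for cid in series[i].member_ids)
    return SplitPlan(train_ids=train_ids, test_ids=test_ids, ratio=ratio,
                     mode="analog_series", trial_index=trial_index, seed=seed)


def random_split(
    cls: ActivityClass, ratio: float, trial_index: int = 0, seed: int = 0
) -> SplitPlan:
    """Seeded random train/test split with ``round(ratio * |cls|)`` training compounds."""
    if len(cls) < 2:
        raise ValueError("need at least two compounds to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n_train = round_half_away(ratio * len(cls))
    if n_train == 0 or n_train == len(cls):
        raise ValueError("degenerate split: empty train or test set")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(cls.compound_ids))
    return SplitPlan(train_ids=tuple(order[:n_train]), test_ids=tuple(order[n_train:]),
                     ratio=ratio, mode="random", trial_index=trial_index, seed=seed)
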