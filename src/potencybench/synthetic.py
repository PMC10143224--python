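"""Synthetic activity-class generator.

Real activity classes from medicinal chemistry have three properties the
benchmark design relies on: (i) most compounds belong to analog series —
groups sharing a core scaffold and differing only by R-groups, the residue
of chemical optimization campaigns; (ii) potency (pIC50) values on [5, 11]
are right-skewed, dominated by the low-micromolar 5–7 range, with the
highest-potency bins sparsest; and (iii) structure and potency are coupled:
analogs have correlated potencies. The generator reproduces exactly these
properties so every downstream stage — curation, modification procedures,
predictors, the multi-trial harness — can be exercised and validated
without any external compound database.

Each series is built from one scaffold with marked attachment points: one
position varies across the series (each member gets a distinct substituent)
and the remaining positions carry fixed substituents, so series members
share a genuine common substructure. Potency follows an additive
structure–activity model::

    pIC50 = base(series) + effect(varying R-group) + N(0, noise_sd),

clipped to [5, 11]. Series base potencies are drawn from a two-component
mixture: uniform on [5, 7) with configurable weight, and a truncated
exponential tail on [7, 11] whose decay makes the highest bins sparsest.
R-group effects are one per-class Gaussian-process draw over substituent
size, so structurally similar substituents carry similar effects
(neighborhood behavior) and identical structures always imply identical
noise-free potency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from ._util import derive_seed
from .chem import parse_mol
from .containers import ActivityClass, CompoundRecord

#: Drug-sized cores (14-24 heavy atoms) with two marked attachment points
#: ([*:1], [*:2]). Positions are structurally distinct on every scaffold so
#: that swapped substituent assignments never coincide.
DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "O=C(Nc1ccc(CN2CCN(CC2)[*:1])cc1)c1cccc([*:2])c1",      # benzamide-piperazine
    "c1ccc2c(c1)nc(N[*:1])n2Cc1ccc([*:2])cc1",              # 1-benzylbenzimidazole
    "O=S(=O)(c1ccc([*:1])cc1)N1CCC(C(=O)N[*:2])CC1",        # arylsulfonyl piperidine amide
    "COc1cc2ncnc(Nc3ccc([*:1])c([*:2])c3)c2cc1OC",          # 4-anilinoquinazoline
    "O=C(N[*:1])c1ccc(-c2ccc([*:2])cc2F)cc1",               # fluorobiphenyl amide
    "Cc1cc(N2CCOCC2)nc(Nc2ccc([*:1])c([*:2])c2)n1",         # morpholinopyrimidine aniline
    "O=C(NCc1ccco1)c1cc([*:1])c2ccccc2c1O[*:2]",            # furfuryl naphthamide
    "CN1CCN(c2ccc(Nc3ncc([*:1])c(-c4cccc([*:2])c4)n3)cc2)CC1",  # pyrimidine biaryl
    "O=C1N(Cc2ccccc2)CCN1c1ccc([*:1])c([*:2])c1",           # benzyl imidazolidinone
    "Cc1onc(-c2ccccc2)c1C(=O)Nc1ccc([*:1])c([*:2])c1",      # isoxazole carboxanilide
    "O=S(=O)(Nc1ccc([*:1])cc1)c1cccc2c1cccc2N[*:2]",        # naphthalene sulfonanilide
    "c1cnc2c(c1)ccc1c2[nH]c2cc([*:1])c([*:2])cc21",         # pyrido-carbazole
)

#: Acyclic substituents with one attachment point, spanning one to eight
#: heavy atoms so that within-series similarities cover the realistic range
#: from near-duplicates (halogen swap on a large core) down to moderately
#: similar analogs (small vs. bulky R-group). Kept ring-free so a single
#: cut at the varying position always leaves every ring in the core.
DEFAULT_SUBSTITUENTS: tuple[str, ...] = (
    "[*]C", "[*]F", "[*]Cl", "[*]Br", "[*]O", "[*]N", "[*]C#N", "[*]OC",
    "[*]CC", "[*]CO", "[*]CCC", "[*]C(C)C", "[*]OCC", "[*]C(F)(F)F",
    "[*]N(C)C", "[*]CC#N", "[*]C(=O)C", "[*]C(=O)N", "[*]CCN", "[*]C(C)O",
    "[*]CCCCC", "[*]CC(C)CC", "[*]OCCOC", "[*]CCN(C)C", "[*]C(=O)OCC",
    "[*]OCC(C)C", "[*]CCCCCC", "[*]CCN(CC)CC", "[*]OCCN(C)C", "[*]CCOCCO",
)

#: Series-size distribution: mostly small analog series, some singletons.
DEFAULT_SERIES_SIZES: Mapping[int, float] = {
    1: 0.10, 2: 0.18, 3: 0.20, 4: 0.18, 5: 0.14, 6: 0.10, 8: 0.06, 10: 0.04,
}


class InfeasibleSeriesError(ValueError):
    """A requested series size exceeds what the substituent library allows."""


#: Probability that a series member is drawn from the homologous cluster
#: around the series' anchor substituent size (rather than from the whole
#: library). Real optimization series are anchored on a cluster of closely
#: related substituents (halogen and homolog swaps) plus a periphery of
#: exploratory, structurally distant analogs; this mix makes within-series
#: redundancy heterogeneous, as in real activity classes.
SERIES_CLUSTER_PROB = 0.65
#: Half-width (heavy atoms) of the homologous cluster around the anchor.
SERIES_CLUSTER_WIDTH = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic activity class.

    ``low_bin_weight`` is the mixture weight of the uniform [5, 7)
    component of the series base-potency distribution; ``tail_scale`` is
    the decay scale (pIC50 units) of the truncated-exponential tail on
    [7, 11]. ``rgroup_effect_sd`` and ``noise_sd`` are in pIC50 units.
    """

    n_compounds: int = 200
    n_series: int = 40
    series_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SERIES_SIZES)
    )
    scaffold_library: tuple[str, ...] = DEFAULT_SCAFFOLDS
    substituent_library: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    low_bin_weight: float = 0.6
    tail_scale: float = 1.1
    rgroup_effect_sd: float = 0.4
    effect_length_scale: float = 1.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_series < 1:
            raise ValueError("n_compounds and n_series must be positive")
        if self.n_series > self.n_compounds:
            raise ValueError("n_series must not exceed n_compounds")
        if not self.scaffold_library or not self.substituent_library:
            raise ValueError("scaffold and substituent libraries must be non-empty")
        if not self.series_size_distribution:
            raise ValueError("series_size_distribution must be non-empty")
        if any(s < 1 for s in self.series_size_distribution):
            raise ValueError("series sizes must be >= 1")
        if not 0.0 <= self.low_bin_weight <= 1.0:
            raise ValueError("low_bin_weight must be in [0, 1]")
        if self.rgroup_effect_sd < 0 or self.noise_sd < 0 or self.tail_scale <= 0:
            raise ValueError("scale parameters must be non-negative")
        if self.effect_length_scale <= 0:
            raise ValueError("effect_length_scale must be positive")


def _tagged(sub_smiles: str, map_num: int) -> Chem.Mol:
    mol = parse_mol(sub_smiles)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(map_num)
    return mol


def _attachment_points(scaffold_smiles: str) -> list[int]:
    mol = parse_mol(scaffold_smiles)
    points = sorted(
        atom.GetAtomMapNum() for atom in mol.GetAtoms() if atom.GetAtomicNum() == 0
    )
    if not points or 0 in points:
        raise ValueError(f"scaffold lacks numbered attachment points: {scaffold_smiles!r}")
    return points


def assemble_structure(scaffold: str, substituents: Mapping[int, str]) -> str:
    """Attach substituents at the scaffold's numbered attachment points.

    Returns the canonical SMILES of the assembled molecule.
    """
    combo = parse_mol(scaffold)
    for map_num, sub in substituents.items():
        combo = Chem.CombineMols(combo, _tagged(sub, map_num))
    zipped = Chem.molzip(combo)
    Chem.SanitizeMol(zipped)
    return Chem.MolToSmiles(zipped)


def _draw_series_sizes(config: GeneratorConfig, rng: np.random.Generator) -> list[int]:
    """Series sizes from the configured categorical, repaired to the exact total."""
    sizes_avail = sorted(config.series_size_distribution)
    probs = np.array([config.series_size_distribution[s] for s in sizes_avail], dtype=float)
    probs = probs / probs.sum()
    capacity = len(config.substituent_library)
    for idx, size in enumerate(sizes_avail):
        if size > capacity and config.series_size_distribution[size] > 0:
            raise InfeasibleSeriesError(
                f"series size {size} exceeds the {capacity} distinct substituents available"
            )
    sizes = list(rng.choice(sizes_avail, size=config.n_series, p=probs))
    sizes = [int(s) for s in sizes]
    # repair the total to n_compounds
    while sum(sizes) < config.n_compounds:
        growable = [i for i, s in enumerate(sizes) if s < capacity]
        if not growable:
            raise InfeasibleSeriesError(
                f"cannot reach {config.n_compounds} compounds: all {config.n_series} "
                f"series already at the library capacity of {capacity}"
            )
        sizes[int(rng.choice(growable))] += 1
    while sum(sizes) > config.n_compounds:
        shrinkable = [i for i, s in enumerate(sizes) if s > 1]
        sizes[int(rng.choice(shrinkable))] -= 1
    return sizes


def _substituent_sizes(library: Sequence[str]) -> np.ndarray:
    sizes = []
    for smi in library:
        mol = parse_mol(smi)
        sizes.append(sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 0))
    return np.array(sizes, dtype=float)


def _draw_rgroup_effects(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-class R-group effect table with neighborhood behavior.

    Effects are one draw from a Gaussian process over substituent heavy-atom
    count with an exponential kernel, so structurally similar substituents
    (e.g. a halogen swap) carry nearly identical potency effects while
    dissimilar ones (methyl vs. a bulky amine chain) may differ strongly —
    the classic similarity principle of structure-activity relationships.
    Marginal effect standard deviation is ``rgroup_effect_sd``.
    """
    h = _substituent_sizes(config.substituent_library)
    K = np.exp(-np.abs(h[:, None] - h[None, :]) / config.effect_length_scale)
    # K is rank-deficient when sizes repeat; use an eigendecomposition sqrt
    w, V = np.linalg.eigh(K)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    return config.rgroup_effect_sd * (root @ rng.standard_normal(len(h)))


def _draw_base_potency(config: GeneratorConfig, rng: np.random.Generator) -> float:
    if rng.random() < config.low_bin_weight:
        return float(rng.uniform(5.0, 7.0))
    # truncated exponential on [7, 11] by inverse CDF: dense near 7, sparse near 11
    tau = config.tail_scale
    u = rng.random()
    return 7.0 + float(-tau * np.log1p(-u * (1.0 - np.exp(-4.0 / tau))))


def generate_activity_class(config: GeneratorConfig, class_id: str = "SYN000") -> ActivityClass:
    """Generate one synthetic activity class of exactly ``config.n_compounds``.

    Fully reproducible from ``config.seed``. Ground-truth series labels are
    stored on each record (``series_id``) and generation internals (series
    base potencies, the R-group effect table) in ``ActivityClass.meta`` so
    that analog-series extraction and the additive potency model can be
    validated against truth; predictors only ever see structures and
    potencies.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _draw_series_sizes(config, rng)
    n_sub = len(config.substituent_library)
    sub_sizes = _substituent_sizes(config.substituent_library)

    # scaffolds are cycled over a seeded shuffle: series get distinct cores
    # whenever n_series <= library size, spreading structural diversity
    scaffold_order = list(rng.permutation(len(config.scaffold_library)))
    effects = _draw_rgroup_effects(config, rng)

    used_combos: set[tuple] = set()
    seen_smiles: set[str] = set()
    records: list[CompoundRecord] = []
    truth_rows: list[dict] = []
    compound_no = 0

    for s_idx, size in enumerate(sizes):
        series_id = f"{class_id}-S{s_idx:03d}"
        scaffold_idx = scaffold_order[s_idx % len(scaffold_order)]
        scaffold = config.scaffold_library[scaffold_idx]
        points = _attachment_points(scaffold)

        combo = None
        for _attempt in range(200):
            varying_pos = int(rng.choice(points))
            fixed = {
                p: int(rng.integers(n_sub)) for p in points if p != varying_pos
            }
            key = (scaffold_idx, varying_pos, tuple(sorted(fixed.items())))
            if key not in used_combos:
                used_combos.add(key)
                combo = (varying_pos, fixed)
                break
        if combo is None:
            raise InfeasibleSeriesError(
                f"series {series_id}: could not find an unused scaffold/substituent combination"
            )
        varying_pos, fixed = combo

        # anchored-cluster sampling: most members come from the homologous
        # cluster around the series anchor size, the rest from anywhere
        anchor = sub_sizes[int(rng.integers(n_sub))]
        cluster = [i for i in range(n_sub) if abs(sub_sizes[i] - anchor) <= SERIES_CLUSTER_WIDTH]
        varying: list[int] = []
        chosen: set[int] = set()
        for _member in range(size):
            pool = [i for i in cluster if i not in chosen] \
                if rng.random() < SERIES_CLUSTER_PROB else []
            if not pool:
                pool = [i for i in range(n_sub) if i not in chosen]
            v = int(rng.choice(pool))
            chosen.add(v)
            varying.append(v)
        base = _draw_base_potency(config, rng)

        for member in range(size):
            v_idx = varying[member]
            subs = {p: config.substituent_library[i] for p, i in fixed.items()}
            subs[varying_pos] = config.substituent_library[v_idx]
            smiles = assemble_structure(scaffold, subs)
            # canonical SMILES is the identity: duplicates (possible across
            # series sharing a scaffold) are regenerated with an unused R-group
            tried = set(varying)
            while smiles in seen_smiles:
                unused = [i for i in range(n_sub) if i not in tried]
                if not unused:
                    raise InfeasibleSeriesError(
                        f"series {series_id}: substituent library exhausted while "
                        "resolving duplicate structures"
                    )
                v_idx = int(rng.choice(unused))
                tried.add(v_idx)
                varying[member] = v_idx
                subs[varying_pos] = config.substituent_library[v_idx]
                smiles = assemble_structure(scaffold, subs)
            seen_smiles.add(smiles)

            noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
            potency = float(np.clip(base + effects[v_idx] + noise, 5.0, 11.0))
            compound_id = f"{class_id}-C{compound_no:04d}"
            compound_no += 1
            records.append(
                CompoundRecord(
                    compound_id=compound_id,
                    class_id=class_id,
                    structure=smiles,
                    potency=round(potency, 6),
                    series_id=series_id,
                )
            )
            truth_rows.append(
                {"compound_id": compound_id, "series_id": series_id,
                 "base": base, "varying_substituent": v_idx}
            )

    cls = ActivityClass(class_id, records, provenance="original", lineage="synthetic")
    cls.meta = {
        "series_sizes": sizes,
        "rgroup_effects": effects.tolist(),
        "truth": truth_rows,
        "config_seed": config.seed,
    }
    return cls


def generate_benchmark_suite(
    n_classes: int, config: GeneratorConfig, seed: int
) -> list[ActivityClass]:
    """Generate independent classes with per-class seeds derived from ``seed``."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    classes = []
    for i in range(n_classes):
        cfg = replace(config, seed=derive_seed(seed, i))
        classes.append(generate_activity_class(cfg, class_id=f"SYN{i:03d}"))
    return classes
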