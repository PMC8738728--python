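"""Missense-variant analysis over a protein domain map and 3D structure.

Covers per-domain variant counts and score statistics, one-way ANOVA of
scores across regions, and a bootstrap test for spatial clustering of
mutated residues on a crystal structure.

The clustering statistic is the mean pairwise C-alpha distance among the
mutated residues (lower = more clustered).  The null distribution draws
equal-size uniform samples, without replacement, from the residues
actually resolved in the structure; the reported p-value carries the
standard +1 correction, p = (1 + #{null <= observed}) / (1 + B), so it can
never be exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import f_oneway

__all__ = [
    "DomainMap",
    "ResidueCoordinates",
    "ClusterTestResult",
    "assign_domain",
    "domain_summary",
    "anova_regions",
    "clustering_test",
    "read_pdb_ca",
]

LINKER = "linker"


@dataclass(frozen=True)
class DomainMap:
    """Non-overlapping named residue intervals; gaps belong to the linker."""

    protein_length: int
    regions: tuple[tuple[str, int, int], ...]

    def __init__(self, protein_length: int, regions) -> None:
        regions = tuple((str(n), int(a), int(b)) for n, a, b in regions)
        object.__setattr__(self, "protein_length", int(protein_length))
        object.__setattr__(self, "regions", regions)
        for name, a, b in regions:
            if not 1 <= a <= b <= self.protein_length:
                raise ValueError(
                    f"region {name}: interval {a}..{b} outside 1..{protein_length}"
                )
        ordered = sorted(regions, key=lambda r: r[1])
        for (n1, _, e1), (n2, s2, _) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"regions {n1} and {n2} overlap")

    @property
    def names(self) -> list[str]:
        return [r[0] for r in self.regions]


def assign_domain(position: int, domain_map: DomainMap) -> str:
    """Region containing a residue, or ``"linker"`` for gaps."""
    if not 1 <= position <= domain_map.protein_length:
        raise ValueError(
            f"residue {position} outside protein (1..{domain_map.protein_length})"
        )
    for name, a, b in domain_map.regions:
        if a <= position <= b:
            return name
    return LINKER


class ResidueCoordinates:
    """Mapping residue number -> C-alpha coordinate (Angstrom)."""

    def __init__(self, mapping: dict[int, np.ndarray]) -> None:
        self._positions = np.array(sorted(mapping), dtype=int)
        self._coords = np.array(
            [mapping[p] for p in self._positions], dtype=float
        ).reshape(-1, 3)

    @property
    def positions(self) -> np.ndarray:
        return self._positions

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    def __len__(self) -> int:
        return len(self._positions)

    def __contains__(self, position: int) -> bool:
        return bool(np.isin(position, self._positions))

    def subset(self, positions) -> np.ndarray:
        """Coordinate array for the given residue numbers (order preserved)."""
        index = {p: i for i, p in enumerate(self._positions)}
        missing = [p for p in positions if p not in index]
        if missing:
            raise KeyError(f"residues without coordinates: {sorted(missing)}")
        return self._coords[[index[p] for p in positions]]


@dataclass
class ClusterTestResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_boot: int
    seed: int | None
    positions: list[int] = field(default_factory=list)


def domain_summary(table: pd.DataFrame, domain_map: DomainMap) -> pd.DataFrame:
    """Per-region variant count, fraction of all variants, and mean score.

    ``table`` needs columns ``position`` and ``score``.  Regions without a
    variant are kept with count 0 so fractions always sum to 1 across the
    returned rows.
    """
    if table.empty:
        raise ValueError("empty variant table")
    regions = table["position"].map(lambda p: assign_domain(int(p), domain_map))
    total = len(table)
    rows = []
    for name in [*domain_map.names, LINKER]:
        mask = regions == name
        count = int(mask.sum())
        rows.append(
            {
                "region": name,
                "count": count,
                "fraction": count / total,
                "mean_score": float(table.loc[mask, "score"].mean()) if count else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def anova_regions(
    table: pd.DataFrame, domain_map: DomainMap, min_per_group: int = 2
) -> tuple[float, float]:
    """One-way ANOVA of scores grouped by domain region."""
    regions = table["position"].map(lambda p: assign_domain(int(p), domain_map))
    groups = [
        g["score"].to_numpy(dtype=float)
        for _, g in table.groupby(regions, observed=True)
        if len(g) >= min_per_group
    ]
    if len(groups) < 2:
        raise ValueError(
            f"ANOVA needs >=2 regions with >={min_per_group} scores each"
        )
    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0:
        return 0.0, 1.0
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within == 0:
        return float("inf"), 0.0
    f, p = f_oneway(*groups)
    return float(f), float(p)


def clustering_test(
    positions,
    coords: ResidueCoordinates,
    n_boot: int = 999,
    seed: int | None = None,
) -> ClusterTestResult:
    """Bootstrap test for spatial clustering of mutated residues.

    Observed statistic: mean pairwise C-alpha distance among the mutated
    residues.  Null: the same statistic for ``n_boot`` uniform draws of
    equally many resolved residues, sampled without replacement.
    """
    positions = [int(p) for p in positions]
    if len(positions) < 2:
        raise ValueError("clustering test needs at least 2 residue positions")
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate residue positions")
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    if len(coords) < len(positions):
        raise ValueError("more mutated positions than resolved residues")
    observed = float(pdist(coords.subset(positions)).mean())
    rng = np.random.default_rng(seed)
    k = len(positions)
    null = np.empty(n_boot)
    all_coords = coords.coords
    n = len(coords)
    for b in range(n_boot):
        idx = rng.choice(n, size=k, replace=False)
        null[b] = pdist(all_coords[idx]).mean()
    p = (1 + int(np.sum(null <= observed))) / (1 + n_boot)
    return ClusterTestResult(
        observed_stat=observed, null_stats=null, p_value=p,
        n_boot=n_boot, seed=seed, positions=positions,
    )


def read_pdb_ca(pdb_path, chain: str) -> ResidueCoordinates:
    """C-alpha coordinates of one chain of a PDB file.

    Altloc 'A' (or blank) is preferred; residues with insertion codes are
    skipped with a warning; a chain without any C-alpha yields an empty
    map with a warning.
    """
    import gemmi

    structure = gemmi.read_structure(str(pdb_path))
    if len(structure) == 0:
        raise ValueError(f"{pdb_path}: no models")
    model = structure[0]
    chain_obj = model.find_chain(chain)
    if chain_obj is None:
        raise ValueError(
            f"{pdb_path}: chain {chain!r} absent "
            f"(available: {[c.name for c in model]})"
        )
    mapping: dict[int, np.ndarray] = {}
    for residue in chain_obj:
        if residue.seqid.icode not in (" ", ""):
            warnings.warn(
                f"{pdb_path}: skipping residue {residue.seqid.num}{residue.seqid.icode} "
                f"with insertion code"
            )
            continue
        ca = None
        for atom in residue:
            if atom.name == "CA" and (not atom.has_altloc() or atom.altloc == "A"):
                ca = atom
                break
        if ca is not None:
            mapping[residue.seqid.num] = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
    if not mapping:
        warnings.warn(f"{pdb_path}: chain {chain!r} has no C-alpha records")
    return ResidueCoordinates(mapping)
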