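"""Synthetic planted-pharmacophore screening datasets.

Generates small active/decoy libraries in which every active contains a
planted pharmacophore fragment (default: an indole attached to a
carbonyl group) embedded in one of a handful of chemotype scaffolds with
random decorations, while decoys combine the same scaffolds and
decorations with non-pharmacophore caps of roughly matched size and
heteroatom content (including near-miss caps such as an indole without
the carbonyl, or a benzoyl without the indole, so the ranking problem is
separable but not trivial).  The query embeds the planted fragment in
its own scaffold.  Everything is deterministic from the seed, so tests
and experiments need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .chemgraph import (DEFAULT_DESCRIPTOR_CONFIG, DatasetRecord, DescriptorConfig,
                        MoleculeGraph, ScreeningDataset, molecule_from_smiles)

import numpy as np

__all__ = ["FixtureSpec", "generate_planted_dataset", "planted_atom_indices",
           "write_manifest", "DEFAULT_FRAGMENT", "DEFAULT_QUERY"]

#: indole-carbonyl pharmacophore motif (indol-3-yl ketone core)
DEFAULT_FRAGMENT = "O=Cc1c[nH]c2ccccc12"
#: the planted fragment embedded in its own (propyl) scaffold
DEFAULT_QUERY = "CCCC(=O)c8c[nH]c9ccccc89"

# chemotype scaffolds; "{dec}" prefix decoration, "{cap}" head group
_SCAFFOLD_TEMPLATES = (
    "{dec}c1ccc(cc1){cap}",      # para-phenylene
    "{dec}C1CCC(CC1){cap}",      # cyclohexane-1,4-diyl
    "{dec}c1ccc(o1){cap}",       # furan-2,5-diyl
    "{dec}C1CCC({cap})C1",       # cyclopentane-1,3-diyl
    "{dec}N1CCN(CC1){cap}",      # piperazine-1,4-diyl
    "{dec}c1ccc(s1){cap}",       # thiophene-2,5-diyl
    "{dec}C1CC(C1){cap}",        # cyclobutane-1,3-diyl
)

_DEFAULT_DECORATIONS = ("", "C", "CC", "CCC", "CCO", "C(C)C", "FC(F)(F)", "N", "OC")

_ACTIVE_CAP = "C(=O)c8c[nH]c9ccccc89"

# near-miss decoy head groups: share the indole or the carbonyl with the
# planted motif, but never the complete indole-carbonyl pattern
_DECOY_CAPS_HARD = (
    "C(=O)c8ccccc8",           # benzoyl: carbonyl without indole
    "c8cc9ccccc9[nH]8",        # indol-2-yl: indole without carbonyl
    "C(=O)Cc8c[nH]c9ccccc89",  # methylene-spaced indole ketone
    "c8c[nH]c9ccccc89",        # indol-3-yl without carbonyl
)

# plainly dissimilar decoy head groups
_DECOY_CAPS_SOFT = (
    "C(=O)N8CCCC8",         # pyrrolidine amide
    "c8ccncc8",             # pyridyl
    "C(=O)OC",              # methyl ester
    "S(=O)(=O)C",           # methylsulfonyl
    "c8ccc9ccccc9c8",       # naphthyl
    "C#N",                  # nitrile
)


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters for one planted-pharmacophore dataset."""

    n_actives: int = 40
    n_decoys: int = 200
    n_clusters: int = 5
    fragment: str = DEFAULT_FRAGMENT
    query: str = DEFAULT_QUERY
    decorations: tuple[str, ...] = _DEFAULT_DECORATIONS
    hard_decoy_fraction: float = 0.5
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_actives:
            raise ValueError("n_clusters must not exceed n_actives")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must lie in [0, 1)")
        if not 0.0 <= self.hard_decoy_fraction <= 1.0:
            raise ValueError("hard_decoy_fraction must lie in [0, 1]")
        if Chem.MolFromSmarts(self.fragment) is None:
            raise ValueError(f"planted fragment {self.fragment!r} does not parse")


def _build(smiles: str, mol_id: str, config: DescriptorConfig) -> MoleculeGraph:
    graph = molecule_from_smiles(smiles, mol_id, config)
    return graph


def generate_planted_dataset(
        spec: FixtureSpec,
        config: DescriptorConfig = DEFAULT_DESCRIPTOR_CONFIG,
) -> tuple[ScreeningDataset, MoleculeGraph]:
    """Generate the dataset and the query; deterministic from spec.seed.

    Actives combine a cluster-specific scaffold, a random decoration and
    the planted-fragment cap; each is verified to substructure-match the
    fragment.  Decoys swap the cap for a non-pharmacophore head group and
    are verified not to match.  A nonzero ``label_noise`` then flips that
    fraction of labels (mislabeled records keep their structures; flipped
    decoys are assigned a random existing cluster id), which degrades the
    achievable ranking quality in a controlled way.
    """
    rng = np.random.default_rng(spec.seed)
    pattern = Chem.MolFromSmarts(spec.fragment)
    records: list[DatasetRecord] = []

    # cluster assignment: every cluster occupied, remainder random
    cluster_of = list(range(spec.n_clusters))
    cluster_of += list(rng.integers(spec.n_clusters, size=spec.n_actives - spec.n_clusters))
    for k, a in enumerate(cluster_of):
        template = _SCAFFOLD_TEMPLATES[a % len(_SCAFFOLD_TEMPLATES)]
        dec = spec.decorations[rng.integers(len(spec.decorations))]
        smiles = template.format(dec=dec, cap=_ACTIVE_CAP)
        mol = _build(smiles, f"active-{k:03d}", config)
        if not mol.mol.HasSubstructMatch(pattern):
            raise ValueError(f"generated active {smiles!r} lost the planted fragment")
        records.append(DatasetRecord(id=mol.source_id, molecule=mol,
                                     label="active", cluster=f"chemotype-{a}"))

    for k in range(spec.n_decoys):
        template = _SCAFFOLD_TEMPLATES[rng.integers(len(_SCAFFOLD_TEMPLATES))]
        dec = spec.decorations[rng.integers(len(spec.decorations))]
        caps = (_DECOY_CAPS_HARD if rng.uniform() < spec.hard_decoy_fraction
                else _DECOY_CAPS_SOFT)
        cap = caps[rng.integers(len(caps))]
        smiles = template.format(dec=dec, cap=cap)
        mol = _build(smiles, f"decoy-{k:03d}", config)
        if mol.mol.HasSubstructMatch(pattern):
            raise ValueError(f"generated decoy {smiles!r} contains the planted fragment")
        records.append(DatasetRecord(id=mol.source_id, molecule=mol, label="decoy"))

    if spec.label_noise > 0:
        n_flip = int(round(spec.label_noise * len(records)))
        flip = rng.choice(len(records), size=n_flip, replace=False)
        cluster_ids = sorted({r.cluster for r in records if r.cluster is not None})
        for idx in flip:
            rec = records[idx]
            if rec.label == "active":
                records[idx] = DatasetRecord(rec.id, rec.molecule, "decoy", None)
            else:
                cluster = cluster_ids[rng.integers(len(cluster_ids))]
                records[idx] = DatasetRecord(rec.id, rec.molecule, "active", cluster)

    query = _build(spec.query, "query", config)
    if not query.mol.HasSubstructMatch(pattern):
        raise ValueError("query must contain the planted fragment")
    return ScreeningDataset(records), query


def planted_atom_indices(query: MoleculeGraph, fragment: str = DEFAULT_FRAGMENT) -> np.ndarray:
    """Query-atom indices matched by the planted fragment (first match)."""
    pattern = Chem.MolFromSmarts(fragment)
    match = query.mol.GetSubstructMatch(pattern)
    if not match:
        raise ValueError("query does not contain the planted fragment")
    return np.array(match, dtype=np.intp)


def write_manifest(dataset: ScreeningDataset, path, delimiter: str = "\t") -> None:
    """Write the standard manifest (id, smiles, label, cluster).

    The cluster field is left empty for records without a cluster (all
    decoys); the file round-trips through ``chemgraph.read_manifest``.
    """
    with open(path, "w") as fh:
        fh.write(delimiter.join(["id", "smiles", "label", "cluster"]) + "\n")
        for rec in dataset.records:
            fh.write(delimiter.join([rec.id, rec.molecule.smiles, rec.label,
                                     rec.cluster or ""]) + "\n")
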