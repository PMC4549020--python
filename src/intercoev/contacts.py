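"""Structure handling: column-residue mapping, distances, contact labels.

Contacts between two proteins are defined on a co-crystal structure under
one of three named definitions:

* ``cbeta8`` — C-beta/C-beta distance strictly less than 8 Angstroms
  (glycine falls back to its C-alpha, the standard convention);
* ``heavy6`` — minimum non-hydrogen atom-atom distance strictly less
  than 6 Angstroms;
* ``cbeta8+functional`` — the cbeta8 criterion *and* at least one of the
  two residues present in a supplied list of functionally annotated
  residues.

When a complex crystallizes with multiple copies of each chain (e.g. an
ABAB tetramer) the distance for a residue pair is the minimum over all
equivalent chain pairings.

Alignment columns are mapped to structure residues by globally aligning
the ungapped reference row against the chain sequence; columns opposite
indels stay unmapped and all cells involving an unmapped column are
masked in the resulting contact map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .errors import MappingError
from .msa import Msa

CONTACT_DEFINITIONS = {"cbeta8": 8.0, "heavy6": 6.0, "cbeta8+functional": 8.0}

ResidueKey = tuple[int, str]  # (author residue number, insertion code)


def read_structure(path, name: str = "structure"):
    """Parse a PDB file; only the first model is used."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(name, str(path))
    return next(structure.get_models())


def chain_residues(model, chain_id: str) -> list:
    """Standard residues of a chain in author order (waters/hets skipped)."""
    chain = model[chain_id]
    return [r for r in chain.get_residues() if r.id[0] == " "]


def chain_sequence(model, chain_id: str) -> tuple[str, list[ResidueKey]]:
    """One-letter sequence of a chain and the matching residue keys."""
    seq = []
    keys: list[ResidueKey] = []
    for res in chain_residues(model, chain_id):
        seq.append(protein_letters_3to1.get(res.get_resname(), "X"))
        keys.append((res.id[1], res.id[2].strip()))
    return "".join(seq), keys


@dataclass
class ResidueMapping:
    """1-based alignment column -> (chain id, residue number, icode)."""

    chain_id: str
    mapping: dict[int, ResidueKey] = field(default_factory=dict)

    def __contains__(self, column: int) -> bool:
        return column in self.mapping

    def __getitem__(self, column: int) -> ResidueKey:
        return self.mapping[column]

    @property
    def mapped_columns(self) -> list[int]:
        return sorted(self.mapping)


def identity_mapping(length: int, chain_id: str) -> ResidueMapping:
    """Column k -> residue k mapping for structures built from an alignment."""
    return ResidueMapping(chain_id, {k: (k, "") for k in range(1, length + 1)})


def map_columns_to_residues(
    msa: Msa,
    reference_row_id: str,
    model,
    chain_id: str,
    min_identity: float = 0.9,
) -> ResidueMapping:
    """Map alignment columns to chain residues via the reference row.

    The ungapped reference row is globally aligned to the chain sequence
    (BLOSUM62, affine gaps).  Columns aligned to a chain residue are
    mapped; columns that are gaps in the reference, or opposite indels,
    stay unmapped.  An aligned identity below ``min_identity`` aborts —
    the reference row likely belongs to a different protein or chain.
    """
    if reference_row_id not in msa.ids:
        raise MappingError(f"reference row {reference_row_id!r} not in alignment")
    row = msa.matrix[msa.ids.index(reference_row_id)]
    ref_cols = [c + 1 for c in range(msa.length) if row[c] != "-"]
    ref_seq = "".join(row[c - 1] for c in ref_cols)
    chain_seq, keys = chain_sequence(model, chain_id)
    if not ref_seq or not chain_seq:
        raise MappingError("empty reference or chain sequence")

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(ref_seq.replace("X", "A"), chain_seq.replace("X", "A"))[0]

    mapping: dict[int, ResidueKey] = {}
    matches = aligned_len = 0
    for (r0, r1), (c0, c1) in zip(*aln.aligned):
        for off in range(r1 - r0):
            ri, ci = r0 + off, c0 + off
            aligned_len += 1
            if ref_seq[ri] == chain_seq[ci]:
                matches += 1
            mapping[ref_cols[ri]] = keys[ci]
    if aligned_len == 0 or matches / aligned_len < min_identity:
        ident = matches / aligned_len if aligned_len else 0.0
        raise MappingError(
            f"reference/chain identity {ident:.2f} below floor {min_identity}; "
            "wrong chain suspected"
        )
    return ResidueMapping(chain_id, mapping)


def _get_residue(model, chain_id: str, key: ResidueKey):
    resnum, icode = key
    try:
        return model[chain_id][(" ", resnum, icode or " ")]
    except KeyError:
        return None


def _rep_atom(residue):
    """C-beta coordinate, falling back to C-alpha (glycine, missing CB)."""
    for name in ("CB", "CA"):
        if name in residue:
            return residue[name].coord
    return None


def residue_distance(
    model, chain_a: str, key_a: ResidueKey, chain_b: str, key_b: ResidueKey,
    mode: str = "cbeta",
) -> float:
    """Distance in Angstroms between two residues; NaN if atoms missing."""
    ra = _get_residue(model, chain_a, key_a)
    rb = _get_residue(model, chain_b, key_b)
    if ra is None or rb is None:
        return float("nan")
    if mode == "cbeta":
        ca = _rep_atom(ra)
        cb = _rep_atom(rb)
        if ca is None or cb is None:
            return float("nan")
        return float(np.linalg.norm(ca - cb))
    if mode == "min_heavy":
        best = math.inf
        for atom_a in ra.get_atoms():
            if atom_a.element == "H":
                continue
            for atom_b in rb.get_atoms():
                if atom_b.element == "H":
                    continue
                d = float(np.linalg.norm(atom_a.coord - atom_b.coord))
                best = min(best, d)
        return best if best < math.inf else float("nan")
    raise ValueError(f"unknown distance mode {mode!r}")


def min_over_equivalent_chains(
    model,
    chains_a: list[str],
    chains_b: list[str],
    key_a: ResidueKey,
    key_b: ResidueKey,
    mode: str = "cbeta",
) -> float:
    """Minimum residue distance over all equivalent chain pairings."""
    if not chains_a or not chains_b:
        raise ValueError("chain groups must be non-empty")
    dists = [
        residue_distance(model, ca, key_a, cb, key_b, mode)
        for ca in chains_a
        for cb in chains_b
    ]
    dists = [d for d in dists if not math.isnan(d)]
    return min(dists) if dists else float("nan")


@dataclass
class ContactMap:
    """Distances and contact labels for all inter-protein column pairs."""

    definition: str
    distances: np.ndarray
    labels: np.ndarray  # boolean; meaningful only where ~mask
    mask: np.ndarray    # True where either column is unmapped

    @property
    def shape(self) -> tuple[int, int]:
        return self.distances.shape

    def n_positives(self) -> int:
        return int(self.labels[~self.mask].sum())

    def proportion_positives(self) -> float:
        n = (~self.mask).sum()
        return self.n_positives() / n if n else float("nan")


def label_contacts(
    mapping_a: ResidueMapping,
    mapping_b: ResidueMapping,
    model,
    L_A: int,
    L_B: int,
    definition: str = "cbeta8",
    functional_residues: set | None = None,
    chain_groups_a: list[str] | None = None,
    chain_groups_b: list[str] | None = None,
) -> ContactMap:
    """Distance matrix and contact labels under a named definition.

    A pair is positive iff its distance is strictly below the definition's
    threshold; for ``cbeta8+functional`` additionally at least one member
    must be in ``functional_residues`` (a set of (chain_id, resnum)
    tuples).  Cells whose columns are unmapped are masked.
    """
    if definition not in CONTACT_DEFINITIONS:
        raise ValueError(
            f"unknown contact definition {definition!r}; "
            f"expected one of {sorted(CONTACT_DEFINITIONS)}"
        )
    if definition == "cbeta8+functional" and functional_residues is None:
        raise ValueError("cbeta8+functional requires a functional residue list")
    threshold = CONTACT_DEFINITIONS[definition]
    mode = "min_heavy" if definition == "heavy6" else "cbeta"
    chains_a = chain_groups_a or [mapping_a.chain_id]
    chains_b = chain_groups_b or [mapping_b.chain_id]

    distances = np.full((L_A, L_B), np.nan)
    labels = np.zeros((L_A, L_B), dtype=bool)
    mask = np.ones((L_A, L_B), dtype=bool)
    for i in range(1, L_A + 1):
        if i not in mapping_a:
            continue
        for j in range(1, L_B + 1):
            if j not in mapping_b:
                continue
            d = min_over_equivalent_chains(
                model, chains_a, chains_b, mapping_a[i], mapping_b[j], mode
            )
            distances[i - 1, j - 1] = d
            if math.isnan(d):
                continue
            mask[i - 1, j - 1] = False
            positive = d < threshold
            if positive and definition == "cbeta8+functional":
                keyA = (mapping_a.chain_id, mapping_a[i][0])
                keyB = (mapping_b.chain_id, mapping_b[j][0])
                positive = keyA in functional_residues or keyB in functional_residues
            labels[i - 1, j - 1] = positive
    return ContactMap(definition, distances, labels, mask)


def write_viewer_attributes(
    residue_values: dict[tuple[str, int], float],
    path,
    attribute: str = "coevolution",
) -> None:
    """Write a UCSF-Chimera-style residue attribute file."""
    with open(path, "w") as fh:
        fh.write(f"attribute: {attribute}\n")
        fh.write("match mode: 1-to-1\n")
        fh.write("recipient: residues\n")
        for (chain, resnum), value in sorted(residue_values.items()):
            fh.write(f"\t/{chain}:{resnum}\t{value:g}\n")


def read_viewer_attributes(path) -> tuple[str, dict[tuple[str, int], float]]:
    """Read back an attribute file written by :func:`write_viewer_attributes`."""
    values: dict[tuple[str, int], float] = {}
    attribute = ""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("attribute:"):
                attribute = line.split(":", 1)[1].strip()
            elif line.startswith("\t/"):
                spec, val = line.strip().split("\t")
                chain, resnum = spec.lstrip("/").split(":")
                values[(chain, int(resnum))] = float(val)
    return attribute, values
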