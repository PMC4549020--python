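"""Synthetic paired alignments with planted coevolving column pairs.

The generator emulates the features of real paired alignments that drive
coevolution benchmarks without any external data:

* rows correlated through a shared random coalescent-style tree;
* per-column substitution-rate heterogeneity (gamma-distributed rates);
* a configurable set of planted inter-protein column pairs whose
  substitutions are coupled with strength ``c`` in [0, 1];
* optional chained couplings i->j->k (i, j in protein A, k in protein B)
  that create an *indirect* inter-protein correlation (i, k), the
  canonical case where direct-coupling methods should outperform MI;
* optional terminal gap runs, to exercise the gap-column filter and the
  identity denominators;
* a toy two-chain structure in PDB format in which exactly the planted
  pairs are spatially close (C-beta 5 A), everything else far (>= 12 A),
  with an optional second copy of each chain so that some contacts are
  realized only through the alternate chain pairing (ABAB-tetramer path).

Substitution process: on each branch a column mutates with probability
min(rate * branch_length, 0.95); a mutation draws a uniformly random
amino acid.  For a planted pair, whenever either member mutates the pair
mutates jointly: the driver column redraws and, with probability ``c``,
the partner switches to a deterministic matched residue (a fixed random
permutation of the alphabet per pair); otherwise the partner redraws
independently.  At c=1 the two columns induce identical row partitions;
at c=0 they are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alphabet import GAP, N_AA, AMINO_ACIDS
from .errors import SimulationError
from .msa import Msa, PairedAlignment

_MUT_CAP = 0.95


@dataclass
class SimConfig:
    """Study conditions for one synthetic paired alignment."""

    n_taxa: int = 256
    L_A: int = 40
    L_B: int = 40
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    chain_triples: list[tuple[int, int, int, float]] = field(default_factory=list)
    rate_shape: float = 2.0      # gamma shape for per-column rates (mean 1)
    tree_scale: float = 1.0      # multiplies all branch lengths
    gap_fraction: float = 0.0    # expected fraction of gap symbols
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise SimulationError("need at least 2 taxa")
        if self.L_A < 1 or self.L_B < 1:
            raise SimulationError("alignment lengths must be positive")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise SimulationError("gap_fraction must be in [0, 1)")
        used_a: set[int] = set()
        used_b: set[int] = set()
        for i, j, c in self.planted_pairs:
            if not (1 <= i <= self.L_A and 1 <= j <= self.L_B):
                raise SimulationError(f"planted pair ({i},{j}) out of range")
            if not 0.0 <= c <= 1.0:
                raise SimulationError("coupling strength must be in [0, 1]")
            if i in used_a or j in used_b:
                raise SimulationError("planted pairs must use disjoint columns")
            used_a.add(i)
            used_b.add(j)
        for i, j, k, c in self.chain_triples:
            if not (1 <= i <= self.L_A and 1 <= j <= self.L_A and 1 <= k <= self.L_B):
                raise SimulationError(f"chain triple ({i},{j},{k}) out of range")
            if len({i, j}) != 2:
                raise SimulationError("chain columns i and j must differ")
            if not 0.0 <= c <= 1.0:
                raise SimulationError("coupling strength must be in [0, 1]")
            cols_a = {i, j}
            if cols_a & used_a or k in used_b:
                raise SimulationError("chain triples must use fresh columns")
            used_a |= cols_a
            used_b.add(k)


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    contact_pairs: list[tuple[int, int]]       # directly coupled inter pairs
    indirect_pairs: list[tuple[int, int]]      # inter pairs coupled only via a chain
    column_rates_A: np.ndarray
    column_rates_B: np.ndarray


def _random_tree(n: int, rng: np.random.Generator, scale: float):
    """Random binary coalescent-style topology with exponential intervals.

    Returns (parent index array, branch lengths, dendropy tree).  Nodes
    0..n-1 are leaves; internal nodes are appended in coalescence order.
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    blen = np.zeros(n_nodes)
    height = np.zeros(n_nodes)
    active = list(range(n))
    depth = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        depth += rng.exponential(2.0 / (k * (k - 1))) * (n / 2.0)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_node
        height[next_node] = depth
        blen[a] = (depth - height[a]) * scale
        blen[b] = (depth - height[b]) * scale
        active[i] = next_node
        active.pop(j)
        next_node += 1

    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n)])
    nodes = [dendropy.Node() for _ in range(n_nodes)]
    for i in range(n):
        nodes[i].taxon = taxa[i]
    for i in range(n_nodes - 1):
        nodes[parent[i]].add_child(nodes[i])
        nodes[i].edge.length = float(blen[i])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[-1]
    return parent, blen, tree


def simulate_paired(config: SimConfig) -> tuple[PairedAlignment, dendropy.Tree, SimTruth]:
    """Evolve a paired alignment down a random tree with planted couplings."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_taxa
    L = config.L_A + config.L_B
    parent, blen, tree = _random_tree(n, rng, config.tree_scale)
    n_nodes = parent.size

    rates = rng.gamma(config.rate_shape, 1.0 / config.rate_shape, size=L)

    # coupling edges: (driver concat col, dependent concat col, c, match map)
    couplings = []
    contact_pairs: list[tuple[int, int]] = []
    indirect_pairs: list[tuple[int, int]] = []
    for i, j, c in config.planted_pairs:
        match = rng.permutation(N_AA)
        couplings.append((i - 1, config.L_A + j - 1, c, match))
        contact_pairs.append((i, j))
    for i, j, k, c in config.chain_triples:
        match1 = rng.permutation(N_AA)
        match2 = rng.permutation(N_AA)
        couplings.append((i - 1, j - 1, c, match1))
        couplings.append((j - 1, config.L_A + k - 1, c, match2))
        contact_pairs.append((j, k))           # j(A)-k(B) is a direct inter pair
        indirect_pairs.append((i, k))          # i(A)-k(B) is only indirectly coupled
    dependent = {dep for _, dep, _, _ in couplings}

    states = np.empty((n_nodes, L), dtype=np.int64)
    states[-1] = rng.integers(0, N_AA, size=L)
    # preorder: internal nodes were appended in coalescence order, so
    # iterating from the root downwards means decreasing node index
    for node in range(n_nodes - 2, -1, -1):
        s = states[parent[node]].copy()
        p_mut = np.minimum(rates * blen[node], _MUT_CAP)
        mutated = rng.random(L) < p_mut
        mutated[list(dependent)] = False  # dependents only move with their driver
        new_states = rng.integers(0, N_AA, size=L)
        s[mutated] = new_states[mutated]
        changed = mutated.copy()
        # couplings are listed driver-before-dependent, so one pass
        # propagates changes down a chain i -> j -> k
        for driver, dep, c, match in couplings:
            if changed[driver]:
                if rng.random() < c:
                    s[dep] = match[s[driver]]
                else:
                    s[dep] = rng.integers(0, N_AA)
                changed[dep] = True
        states[node] = s

    leaf_codes = states[:n]
    chars = np.array(list(AMINO_ACIDS), dtype="U1")[leaf_codes]

    if config.gap_fraction > 0:
        max_run = max(1, int(round(2 * config.gap_fraction * L)))
        for row in range(n):
            run = int(rng.integers(0, max_run + 1))
            if run == 0:
                continue
            if rng.random() < 0.5:
                chars[row, :run] = GAP
            else:
                chars[row, L - run:] = GAP

    ids = [f"t{i + 1}" for i in range(n)]
    msaA = Msa(ids, chars[:, : config.L_A], label="protA")
    msaB = Msa(list(ids), chars[:, config.L_A :], label="protB")
    truth = SimTruth(
        contact_pairs=sorted(contact_pairs),
        indirect_pairs=sorted(indirect_pairs),
        column_rates_A=rates[: config.L_A],
        column_rates_B=rates[config.L_A :],
    )
    return PairedAlignment(msaA, msaB), tree, truth


_SPACING = 30.0       # between consecutive residues within a chain
_FAR_OFFSET = 200.0   # default separation between the two chains
_CONTACT_CB = 5.0     # planted C-beta distance
_COPY_SHIFT = 500.0   # z-offset of the second copy of each chain


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z) -> str:
    return (
        f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {name[0]:>2s}\n"
    )


def toy_structure(
    contact_pairs: list[tuple[int, int]],
    L_A: int,
    L_B: int,
    path,
    tetramer: bool = False,
    contact_distance: float = _CONTACT_CB,
    seq_a: str | None = None,
    seq_b: str | None = None,
) -> None:
    """Write a toy two-chain (or four-chain) PDB structure.

    One residue per alignment column; planted pairs sit at C-beta
    distance ``contact_distance`` and every other inter-chain pair is far
    (>= 12 A).  With ``tetramer=True`` chains C and D replicate A and B at
    a large offset and every second planted contact is realized only
    between chain A and chain D, so recovering all contacts requires the
    minimum-distance path over equivalent chains.
    """
    for i, j in contact_pairs:
        if not (1 <= i <= L_A and 1 <= j <= L_B):
            raise SimulationError(f"contact pair ({i},{j}) out of range")
    if contact_distance >= 12.0:
        raise SimulationError("contact distance must stay below the far floor (12 A)")
    aa3 = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    seq_a = seq_a or "A" * L_A
    seq_b = seq_b or "A" * L_B

    # chain A: residue i at x = spacing*i, y = 0
    coords_a = {i: np.array([_SPACING * i, 0.0, 0.0]) for i in range(1, L_A + 1)}
    coords_b = {j: np.array([_SPACING * j, _FAR_OFFSET, 0.0]) for j in range(1, L_B + 1)}
    b_z: dict[int, float] = {}
    for idx, (i, j) in enumerate(sorted(contact_pairs)):
        alt = tetramer and idx % 2 == 1
        z = -_COPY_SHIFT if alt else 0.0
        coords_b[j] = coords_a[i] + np.array([0.0, contact_distance, z])
        b_z[j] = z

    lines = []
    serial = 1

    def emit(chain, seq, coords, zshift=0.0):
        nonlocal serial
        for idx in sorted(coords):
            cb = coords[idx] + np.array([0.0, 0.0, zshift])
            ca = cb + np.array([0.0, -1.5, 0.0])
            resname = aa3.get(seq[idx - 1], "ALA")
            if resname == "GLY":
                lines.append(_pdb_atom(serial, "CA", resname, chain, idx, *cb))
                serial += 1
            else:
                lines.append(_pdb_atom(serial, "CA", resname, chain, idx, *ca))
                serial += 1
                lines.append(_pdb_atom(serial, "CB", resname, chain, idx, *cb))
                serial += 1
        lines.append(f"TER   {serial:5d}\n")
        serial += 1

    emit("A", seq_a, coords_a)
    emit("B", seq_b, coords_b)
    if tetramer:
        emit("C", seq_a, coords_a, zshift=_COPY_SHIFT)
        emit("D", seq_b, coords_b, zshift=_COPY_SHIFT)
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
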