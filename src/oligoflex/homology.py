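"""Cross-homologue structure comparison.

Utilities for comparing two orthologous structures: extract a chain's
one-letter sequence, compute percent sequence identity from a global
pairwise alignment (Biopython aligner), and superpose the Cα traces of
aligned residue pairs to get a cross-homologue RMSD.  These are the
operations behind statements like "52% identity, Cα RMSD about 1 Å"
for a mesophile/thermophile pair.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .collective_variables import superpose
from .structure_io import Structure

__all__ = ["chain_sequence", "sequence_identity", "aligned_ca_rmsd"]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "HSD": "H", "HSE": "H", "HSP": "H",
}


def chain_sequence(structure: Structure, chain: str) -> tuple[str, list[int]]:
    """One-letter sequence of a chain plus the resid of each position.

    Only residues with a Cα atom count; unknown residue types become 'X'.
    """
    seq, resids = [], []
    for i, a in enumerate(structure.atoms):
        if a.chain == chain and a.name == "CA" and a.element != "H":
            seq.append(_THREE_TO_ONE.get(a.resname, "X"))
            resids.append(a.resid)
    if not seq:
        raise ValueError(f"chain {chain!r} has no Cα atoms")
    return "".join(seq), resids


def _aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    al.mode = "global"
    return al


def _aligned_pairs(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    aln = _aligner().align(seq_a, seq_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over the global alignment (matches / aligned columns)."""
    pairs = _aligned_pairs(seq_a, seq_b)
    if not pairs:
        return 0.0
    matches = sum(seq_a[i] == seq_b[j] for i, j in pairs)
    return 100.0 * matches / len(pairs)


def aligned_ca_rmsd(
    struct_a: Structure, chain_a: str, struct_b: Structure, chain_b: str
) -> float:
    """Cα RMSD over sequence-aligned residue pairs after superposition (Å)."""
    seq_a, res_a = chain_sequence(struct_a, chain_a)
    seq_b, res_b = chain_sequence(struct_b, chain_b)
    pairs = _aligned_pairs(seq_a, seq_b)
    if len(pairs) < 3:
        raise ValueError("fewer than 3 aligned residue pairs")
    ca_a = {(a.chain, a.resid): k for k, a in enumerate(struct_a.atoms) if a.name == "CA"}
    ca_b = {(a.chain, a.resid): k for k, a in enumerate(struct_b.atoms) if a.name == "CA"}
    xa = np.array([struct_a.coords[ca_a[(chain_a, res_a[i])]] for i, _ in pairs])
    xb = np.array([struct_b.coords[ca_b[(chain_b, res_b[j])]] for _, j in pairs])
    return superpose(xa, xb).rmsd
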