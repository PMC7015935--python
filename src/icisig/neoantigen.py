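"""Candidate neo-antigen peptide enumeration from missense mutations.

A missense mutation creates mutant 9-11-mer peptides; every window of each
length that contains the altered residue and lies fully inside the protein
is a candidate for MHC class I presentation.  Binding-affinity prediction
is an external step (e.g. a netMHCpan run against H2-Kb): this module emits
the mutant and matched wild-type peptides as a TSV contract for such a
predictor and filters the returned affinities at the conventional 500 nM
cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
DEFAULT_LENGTHS = (9, 10, 11)

__all__ = [
    "MissenseMutation",
    "PeptideCandidate",
    "apply_missense",
    "enumerate_mutant_peptides",
    "filter_binders",
    "read_proteins",
    "read_mutations",
    "write_candidates",
]


@dataclass(frozen=True)
class MissenseMutation:
    """A single amino-acid substitution (1-based position)."""

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa not in AMINO_ACIDS or self.alt_aa not in AMINO_ACIDS:
            raise ValueError(
                f"amino acids must be in the 20-letter alphabet: "
                f"{self.ref_aa!r}>{self.alt_aa!r}"
            )
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt amino acids must differ")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")


@dataclass(frozen=True)
class PeptideCandidate:
    """A mutant peptide window with its matched wild-type counterpart."""

    sequence: str
    wt_sequence: str
    length: int
    mutated_offset: int  # 1-based position of the variant within the peptide
    mutation_id: str

    def __post_init__(self) -> None:
        if not 9 <= self.length <= 11 or len(self.sequence) != self.length:
            raise ValueError("peptide length must be 9-11 and match sequence")
        if not 1 <= self.mutated_offset <= self.length:
            raise ValueError("mutated_offset out of range")


def apply_missense(protein: str, mut: MissenseMutation) -> str:
    """Apply a single-residue substitution, validating the reference."""
    if not 1 <= mut.position <= len(protein):
        raise ValueError(
            f"position {mut.position} out of range for protein of length "
            f"{len(protein)}"
        )
    found = protein[mut.position - 1]
    if found != mut.ref_aa:
        raise ValueError(
            f"reference mismatch at position {mut.position}: expected "
            f"{mut.ref_aa!r}, found {found!r}"
        )
    return protein[: mut.position - 1] + mut.alt_aa + protein[mut.position :]


def enumerate_mutant_peptides(
    mutant_protein: str,
    wt_protein: str,
    position: int,
    mutation_id: str = "",
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> list[PeptideCandidate]:
    """All 9-11-mer windows containing the mutated residue.

    For each length k, every window fully inside the protein that covers
    ``position`` (1-based) is returned, so the mutated amino acid occupies
    each possible position within the peptide.  Candidates are ordered by
    length then start; duplicate (sequence, length) pairs are kept once.
    """
    n = len(mutant_protein)
    if not 1 <= position <= n:
        raise ValueError(f"position {position} out of range for length {n}")
    if n < min(lengths):
        warnings.warn(
            f"protein of length {n} shorter than the minimum peptide length",
            stacklevel=2,
        )
        return []
    out: list[PeptideCandidate] = []
    seen: set[tuple[str, int]] = set()
    for k in sorted(lengths):
        if k > n:
            continue
        lo = max(0, position - k)  # 0-based start range covering position-1
        hi = min(n - k, position - 1)
        for start in range(lo, hi + 1):
            seq = mutant_protein[start : start + k]
            key = (seq, k)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                PeptideCandidate(
                    sequence=seq,
                    wt_sequence=wt_protein[start : start + k],
                    length=k,
                    mutated_offset=position - start,
                    mutation_id=mutation_id,
                )
            )
    return out


def filter_binders(
    records: pd.DataFrame | Iterable[dict], threshold_nm: float = 500.0
) -> pd.DataFrame:
    """Keep affinity records with predicted IC50 strictly below the cutoff.

    ``records`` needs columns ``peptide``, ``allele``, ``predicted_ic50``
    (nM, > 0).
    """
    df = pd.DataFrame(records)
    if df.empty:
        return df
    if (df["predicted_ic50"] <= 0).any():
        raise ValueError("predicted IC50 values must be positive")
    return df[df["predicted_ic50"] < threshold_nm].reset_index(drop=True)


def read_proteins(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA into {id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_mutations(path: str | Path) -> list[MissenseMutation]:
    """Read missense mutations from TSV (protein_id, position, ref_aa, alt_aa)."""
    df = pd.read_csv(path, sep="\t")
    return [
        MissenseMutation(
            protein_id=str(r.protein_id),
            position=int(r.position),
            ref_aa=str(r.ref_aa),
            alt_aa=str(r.alt_aa),
        )
        for r in df.itertuples()
    ]


def write_candidates(candidates: Sequence[PeptideCandidate], path: str | Path) -> None:
    """Write mutant/wild-type peptide candidates as TSV."""
    pd.DataFrame([c.__dict__ for c in candidates]).to_csv(path, sep="\t", index=False)
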