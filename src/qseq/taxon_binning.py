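"""Reference-based taxon assignment for amplicon reads.

A deliberately simple binner: each read's post-primer amplicon region is
globally aligned (edit distance, unit costs) against every reference
amplicon, and the read is assigned to the best-identity reference, or
"unassigned" below a minimum identity.  This stands in for full
database classification, which is out of scope; it is exact for mock
and simulated communities whose references are well separated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import edlib
from Bio import SeqIO

from .core_model import TagCountSummary
from .tag_extraction import TagObservation, count_unique_tags

__all__ = [
    "ReferenceTaxon",
    "UNASSIGNED",
    "load_references",
    "assign_taxon",
    "assign_taxa",
    "tally_by_taxon",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class ReferenceTaxon:
    """One reference amplicon (e.g. a 16S V4 region) with a stable identifier."""

    taxon_id: str
    name: str
    amplicon_sequence: str

    def __post_init__(self) -> None:
        seq = self.amplicon_sequence.upper()
        if not seq:
            raise ValueError(f"reference {self.taxon_id}: empty amplicon sequence")
        bad = set(seq) - _ACGT
        if bad:
            raise ValueError(
                f"reference {self.taxon_id}: non-ACGT characters {sorted(bad)}"
            )
        object.__setattr__(self, "amplicon_sequence", seq)


def load_references(path: Union[str, Path]) -> List[ReferenceTaxon]:
    """Read a reference FASTA; record id is the taxon_id, description the name."""
    refs = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate taxon_id {record.id!r} in {path}")
        seen.add(record.id)
        refs.append(
            ReferenceTaxon(
                taxon_id=record.id,
                name=record.description or record.id,
                amplicon_sequence=str(record.seq).upper(),
            )
        )
    return refs


def _identity(query: str, reference: str) -> float:
    """Global-alignment identity: 1 - edit_distance / max(len)."""
    dist = edlib.align(query, reference, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(query), len(reference))


def assign_taxon(
    read_amplicon: str,
    references: Sequence[ReferenceTaxon],
    min_identity: float = 0.97,
) -> Tuple[str, float]:
    """Assign one amplicon to the best-matching reference.

    Returns (taxon_id, identity); taxon_id is ``"unassigned"`` when the
    best identity falls below ``min_identity``.  Ties go to the first
    reference in input order (logged).
    """
    if not references:
        raise ValueError("references must be non-empty")
    if not (0.0 < min_identity <= 1.0):
        raise ValueError(f"min_identity must be in (0, 1], got {min_identity}")
    if not read_amplicon:
        raise ValueError("empty read amplicon")
    query = read_amplicon.upper()
    best_id, best_ident = UNASSIGNED, -1.0
    tied = False
    for ref in references:
        ident = _identity(query, ref.amplicon_sequence)
        if ident > best_ident:
            best_id, best_ident = ref.taxon_id, ident
            tied = False
        elif ident == best_ident:
            tied = True
    if tied:
        logger.debug("tie at identity %.4f resolved to first reference %s", best_ident, best_id)
    if best_ident < min_identity:
        return UNASSIGNED, best_ident
    return best_id, best_ident


def assign_taxa(
    observations: Iterable[TagObservation],
    references: Sequence[ReferenceTaxon],
    min_identity: float = 0.97,
) -> List[TagObservation]:
    """Fill in group_id for every observation from its amplicon region.

    Identical amplicon strings are aligned once and the result cached —
    with low sequencing-error rates most reads are exact duplicates of a
    reference, so this collapses the alignment workload by orders of
    magnitude.
    """
    cache: Dict[str, str] = {}
    out = []
    for obs in observations:
        if obs.amplicon is None:
            raise ValueError(f"observation {obs.read_id} lacks an amplicon region")
        taxon = cache.get(obs.amplicon)
        if taxon is None:
            taxon, _ = assign_taxon(obs.amplicon, references, min_identity)
            cache[obs.amplicon] = taxon
        obs.group_id = taxon
        out.append(obs)
    return out


def tally_by_taxon(
    observations: Sequence[TagObservation],
    collapse_hamming1: bool = False,
) -> List[TagCountSummary]:
    """Per-taxon unique-tag counts.

    Tag identity is scoped within taxon: the same octamer observed in two
    taxa is two distinct labels, because labeling happens per molecule and
    molecules of different taxa are distinguishable by sequence.  The sum
    of per-taxon reads equals the number of observations (conservation).
    """
    return count_unique_tags(observations, collapse_hamming1=collapse_hamming1)
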