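"""Truth-tracked simulator for random-barcode amplicon sequencing.

Emulates the computational half of the quantitative-sequencing workflow:

1. *Stochastic labeling* — each of N template molecules per taxon draws
   one tag uniformly and independently from the 4^L tag space (optionally
   with sub-unit labeling efficiency).
2. *Amplification bias* — per-taxon weights skew the share of reads each
   taxon receives, emulating differential PCR efficiency.  Tags are fixed
   before amplification, so bias distorts read counts but not tag sets —
   the property the tag-counting estimator exploits.  An optional
   per-molecule Bernoulli-doubling PCR-cycle mode is available for
   realism studies.
3. *Sequencing* — reads sample labeled molecules; each read is the full
   construct (adapter + tag + forward-primer realization + reference
   amplicon + reverse-complemented reverse-primer realization) with
   independent uniform per-base substitution errors and constant Q37
   qualities.

Every emitted read is provenance-tracked back to its template molecule,
so extraction, binning, and estimation can be validated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core_model import BarcodeConfig
from .tag_extraction import ADAPTER_F, U515F, U806R, IUPAC_SETS, PrimerSpec
from .taxon_binning import ReferenceTaxon

__all__ = [
    "SimulationConfig",
    "TaxonTruth",
    "SimulationTruth",
    "SimulatedRead",
    "mock_reference_taxa",
    "preset_config",
    "label_templates",
    "simulate",
    "sample_reads",
    "write_fastq_and_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Constant FASTQ quality character (Phred 37); no operation consumes qualities.
QUALITY_CHAR = "F"


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sequencing run.

    Defaults mirror the protocol's operating point: octamer tags
    (C = 65,536), complete labeling, ten reads per template copy, and an
    Illumina-like 5x10^-4 per-base substitution rate.
    """

    taxa: Tuple[ReferenceTaxon, ...]
    template_copies: Dict[str, int]
    barcode: BarcodeConfig = BarcodeConfig(8)
    labeling_efficiency: float = 1.0
    amplification_weights: Optional[Dict[str, float]] = None
    reads_multiplier: float = 10.0
    per_base_error: float = 5e-4
    seed: int = 0
    amplification_mode: str = "weights"  # or "cycles"
    pcr_cycles: int = 40

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("at least one taxon is required")
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("taxon_ids must be unique")
        missing = set(ids) - set(self.template_copies)
        if missing:
            raise ValueError(f"template_copies missing for taxa {sorted(missing)}")
        total = sum(self.template_copies[t] for t in ids)
        if total < 1:
            raise ValueError("total template copies must be >= 1")
        if not (0.0 < self.labeling_efficiency <= 1.0):
            raise ValueError("labeling_efficiency must be in (0, 1]")
        if self.reads_multiplier <= 0:
            raise ValueError("reads_multiplier must be positive")
        if not (0.0 <= self.per_base_error < 1.0):
            raise ValueError("per_base_error must be in [0, 1)")
        if self.amplification_mode not in {"weights", "cycles"}:
            raise ValueError("amplification_mode must be 'weights' or 'cycles'")

    def weight(self, taxon_id: str) -> float:
        if self.amplification_weights is None:
            return 1.0
        w = self.amplification_weights.get(taxon_id, 1.0)
        if w <= 0:
            raise ValueError(f"amplification weight for {taxon_id} must be positive")
        return w

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["taxa"] = [t.taxon_id for t in self.taxa]
        d["barcode"] = {"tag_length": self.barcode.tag_length,
                       "tag_space": self.barcode.tag_space}
        return d


@dataclass
class TaxonTruth:
    """Ground truth for one taxon: templates, labeled molecules, and their tags."""

    taxon_id: str
    template_copies: int
    tags: List[str]  # tag of molecule i (labeled molecules only)
    h_true: int      # distinct tags among labeled molecules

    @property
    def labeled_molecules(self) -> int:
        return len(self.tags)


@dataclass
class SimulationTruth:
    """Full provenance record emitted alongside the reads."""

    per_taxon: Dict[str, TaxonTruth]
    # (read_id, taxon_id, molecule_index) per emitted read, in emission order
    provenance: List[Tuple[str, str, int]]
    seed: int


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str


# --------------------------------------------------------------------------
# Bundled synthetic mock references


def mock_reference_taxa(amplicon_length: int = 250) -> List[ReferenceTaxon]:
    """Six synthetic reference amplicons playing the roles of the mock species.

    The sequences are deterministic pseudo-random 250-mers (internal fixed
    seed), NOT real 16S V4 sequences: random 250-mers are pairwise ~25%
    identical, far below any assignment threshold, which makes binning
    behavior on them exact and easy to reason about.
    """
    names = [
        ("S_tokodaii", "Sulfolobus tokodaii (synthetic stand-in)"),
        ("M_jannaschii", "Methanocaldococcus jannaschii (synthetic stand-in)"),
        ("B_subtilis", "Bacillus subtilis (synthetic stand-in)"),
        ("S_avermitilis", "Streptomyces avermitilis (synthetic stand-in)"),
        ("P_denitrificans", "Paracoccus denitrificans (synthetic stand-in)"),
        ("H_elongata", "Halomonas elongata (synthetic stand-in)"),
    ]
    rng = np.random.default_rng(160915)  # fixed: references are constants
    refs = []
    for taxon_id, name in names:
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, amplicon_length))
        refs.append(ReferenceTaxon(taxon_id, name, seq))
    return refs


def _split_total(total: int, weights: Sequence[float]) -> List[int]:
    """Integer split of `total` proportional to weights (largest remainder)."""
    raw = [total * w / sum(weights) for w in weights]
    floors = [int(x) for x in raw]
    remainder = total - sum(floors)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - floors[i], reverse=True)
    for i in order[:remainder]:
        floors[i] += 1
    return floors


def preset_config(
    name: str,
    seed: int = 0,
    ratio: Optional[Tuple[int, int]] = None,
    total_copies: int = 20_000,
    **overrides,
) -> SimulationConfig:
    """Named study designs.

    - ``mock6-equal``: six-taxon equimolar community, total 2.0x10^4 copies.
    - ``mock6-skew``: six-taxon skewed community (weights 6:3:1:5:4:2 of the
      same total), the graded-abundance design.
    - ``two-species-ratio``: two taxa at ``ratio`` (e.g. (1, 99) .. (99, 1))
      of the total.
    """
    refs = mock_reference_taxa()
    if name == "mock6-equal":
        copies = _split_total(total_copies, [1] * 6)
        taxa = refs
    elif name == "mock6-skew":
        copies = _split_total(total_copies, [6, 3, 1, 5, 4, 2])
        taxa = refs
    elif name == "two-species-ratio":
        if ratio is None:
            raise ValueError("two-species-ratio preset requires ratio=(a, b)")
        a, b = ratio
        if a <= 0 or b <= 0:
            raise ValueError("ratio parts must be positive")
        copies = _split_total(total_copies, [a, b])
        taxa = refs[:2]
    else:
        raise ValueError(f"unknown preset {name!r}")
    template_copies = {t.taxon_id: c for t, c in zip(taxa, copies)}
    return SimulationConfig(
        taxa=tuple(taxa), template_copies=template_copies, seed=seed, **overrides
    )


# --------------------------------------------------------------------------
# Labeling


def _tag_codes_to_strings(codes: np.ndarray, tag_length: int) -> List[str]:
    """Decode integer tags (base-4 little-endian) to ACGT strings."""
    if codes.size == 0:
        return []
    digits = np.empty((codes.size, tag_length), dtype=np.uint8)
    rem = codes.astype(np.int64).copy()
    for j in range(tag_length):
        digits[:, j] = rem % 4
        rem //= 4
    chars = _BASES[digits]
    width = tag_length
    return [b.decode("ascii") for b in chars.view(f"S{width}").ravel()]


def _label_tag_codes(
    n_templates: int, barcode: BarcodeConfig, efficiency: float, rng: np.random.Generator
) -> np.ndarray:
    """Integer tag codes for the labeled subset of n_templates molecules."""
    labeled = int(round(efficiency * n_templates))
    return rng.integers(0, barcode.tag_space, size=labeled, dtype=np.int64)


def label_templates(
    n_templates: int,
    barcode: BarcodeConfig,
    efficiency: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[int, str]]:
    """Stochastically label templates: uniform independent draws from 4^L tags.

    Returns (molecule_id, tag) pairs for the ~efficiency*N molecules that
    received a tag.  The distinct-tag count follows the occupancy
    distribution with mean C*(1-(1-1/C)^N) at efficiency 1.
    """
    if n_templates < 0:
        raise ValueError(f"n_templates must be >= 0, got {n_templates}")
    if rng is None:
        rng = np.random.default_rng(0)
    codes = _label_tag_codes(n_templates, barcode, efficiency, rng)
    tags = _tag_codes_to_strings(codes, barcode.tag_length)
    return list(enumerate(tags))


# --------------------------------------------------------------------------
# Read sampling


def _realize_primer(primer: PrimerSpec, rng: np.random.Generator) -> str:
    """Fix one concrete expansion of a degenerate primer (per template/taxon)."""
    out = []
    for code in primer.sequence:
        options = sorted(IUPAC_SETS[code])
        out.append(options[rng.integers(0, len(options))] if len(options) > 1 else options[0])
    return "".join(out)


def _apply_substitutions(
    mat: np.ndarray, per_base_error: float, rng: np.random.Generator
) -> None:
    """In-place uniform substitution errors on an ACGT byte matrix.

    The number of errors is drawn binomially for the whole block and the
    positions uniformly with replacement — indistinguishable from per-base
    Bernoulli trials at realistic rates.
    """
    if per_base_error <= 0 or mat.size == 0:
        return
    k = rng.binomial(mat.size, per_base_error)
    if k == 0:
        return
    flat = mat.reshape(-1)
    pos = rng.integers(0, flat.size, size=k)
    old = _BASE_INDEX[flat[pos]].astype(np.int64)
    new = (old + rng.integers(1, 4, size=k)) % 4
    flat[pos] = _BASES[new]


def _per_molecule_pcr_copies(
    n_molecules: int, efficiency: float, cycles: int, rng: np.random.Generator
) -> np.ndarray:
    """Galton-Watson per-molecule PCR: each copy duplicates with prob `efficiency`
    per cycle.  Returns final copy numbers (used as read-sampling weights)."""
    copies = np.ones(n_molecules, dtype=np.int64)
    for _ in range(cycles):
        copies = copies + rng.binomial(copies, efficiency)
    return copies


def simulate(config: SimulationConfig) -> Tuple[List[SimulatedRead], SimulationTruth]:
    """Run the full generative model and return reads plus ground truth.

    Deterministic given the config (including its seed): identical configs
    produce byte-identical reads and truth records.
    """
    rng = np.random.default_rng(config.seed)
    barcode = config.barcode
    taxa = list(config.taxa)

    # Per-taxon concrete primer realizations (a real template has fixed bases
    # at the primer sites; degeneracy varies between taxa, not within).
    fwd_real = {t.taxon_id: _realize_primer(U515F, rng) for t in taxa}
    rev_real = {t.taxon_id: _realize_primer(U806R, rng) for t in taxa}

    # Labeling, in declared taxa order.
    tag_codes: Dict[str, np.ndarray] = {}
    per_taxon: Dict[str, TaxonTruth] = {}
    for t in taxa:
        n = config.template_copies[t.taxon_id]
        codes = _label_tag_codes(n, barcode, config.labeling_efficiency, rng)
        tag_codes[t.taxon_id] = codes
        per_taxon[t.taxon_id] = TaxonTruth(
            taxon_id=t.taxon_id,
            template_copies=n,
            tags=_tag_codes_to_strings(codes, barcode.tag_length),
            h_true=int(np.unique(codes).size),
        )

    labeled_counts = np.array([tag_codes[t.taxon_id].size for t in taxa], dtype=float)
    if labeled_counts.sum() == 0:
        raise ValueError("no labeled molecules: nothing to sequence")

    total_templates = sum(config.template_copies[t.taxon_id] for t in taxa)
    n_reads = int(round(config.reads_multiplier * total_templates))

    # Optional per-molecule PCR-cycle weights; default taxon-level weights.
    molecule_weights: Dict[str, Optional[np.ndarray]] = {t.taxon_id: None for t in taxa}
    if config.amplification_mode == "cycles":
        taxon_share = np.empty(len(taxa))
        for i, t in enumerate(taxa):
            eff = min(config.weight(t.taxon_id), 1.0)
            w = _per_molecule_pcr_copies(tag_codes[t.taxon_id].size, eff, config.pcr_cycles, rng)
            molecule_weights[t.taxon_id] = w
            taxon_share[i] = w.sum()
    else:
        taxon_share = labeled_counts * np.array([config.weight(t.taxon_id) for t in taxa])
    probs = taxon_share / taxon_share.sum()

    taxon_of_read = rng.choice(len(taxa), size=n_reads, p=probs)

    reads: List[SimulatedRead] = [None] * n_reads  # type: ignore[list-item]
    provenance: List[Tuple[str, str, int]] = [None] * n_reads  # type: ignore[list-item]
    read_ids = [f"read{i:08d}" for i in range(n_reads)]
    tag_start = len(ADAPTER_F)
    tag_end = tag_start + barcode.tag_length

    for ti, t in enumerate(taxa):
        rows = np.flatnonzero(taxon_of_read == ti)
        if rows.size == 0:
            continue
        codes = tag_codes[t.taxon_id]
        mw = molecule_weights[t.taxon_id]
        if mw is None:
            mol = rng.integers(0, codes.size, size=rows.size)
        else:
            mol = rng.choice(codes.size, size=rows.size, p=mw / mw.sum())
        template = (
            ADAPTER_F
            + "?" * barcode.tag_length
            + fwd_real[t.taxon_id]
            + t.amplicon_sequence
            + _revcomp(rev_real[t.taxon_id])
        )
        width = len(template)
        mat = np.tile(np.frombuffer(template.encode("ascii"), dtype=np.uint8), (rows.size, 1))
        # Paint each read's tag from its molecule's tag code.
        digits = np.empty((rows.size, barcode.tag_length), dtype=np.int64)
        rem = codes[mol].copy()
        for j in range(barcode.tag_length):
            digits[:, j] = rem % 4
            rem //= 4
        mat[:, tag_start:tag_end] = _BASES[digits]
        _apply_substitutions(mat, config.per_base_error, rng)
        qual = QUALITY_CHAR * width
        seqs = [b.decode("ascii") for b in mat.view(f"S{width}").ravel()]
        for r, m, s in zip(rows, mol, seqs):
            reads[r] = SimulatedRead(read_ids[r], s, qual)
            provenance[r] = (read_ids[r], t.taxon_id, int(m))

    truth = SimulationTruth(per_taxon=per_taxon, provenance=provenance, seed=config.seed)
    return reads, truth


def sample_reads(
    labeled: Dict[str, List[Tuple[int, str]]],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[SimulatedRead]:
    """Sample reads from pre-labeled molecules (thin wrapper over simulate's
    sampling stage, for callers that labeled molecules themselves).

    Each read picks a taxon with probability proportional to labeled-template
    share times amplification weight, then a molecule uniformly within the
    taxon.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    taxa = list(config.taxa)
    fwd_real = {t.taxon_id: _realize_primer(U515F, rng) for t in taxa}
    rev_real = {t.taxon_id: _realize_primer(U806R, rng) for t in taxa}
    counts = np.array([len(labeled.get(t.taxon_id, [])) for t in taxa], dtype=float)
    if counts.sum() == 0:
        raise ValueError("at least one labeled molecule is required")
    weights = counts * np.array([config.weight(t.taxon_id) for t in taxa])
    probs = weights / weights.sum()
    total = sum(config.template_copies[t.taxon_id] for t in taxa)
    n_reads = int(round(config.reads_multiplier * total))
    taxon_of_read = rng.choice(len(taxa), size=n_reads, p=probs)
    out = []
    for i in range(n_reads):
        t = taxa[taxon_of_read[i]]
        mols = labeled[t.taxon_id]
        _, tag = mols[rng.integers(0, len(mols))]
        seq = (
            ADAPTER_F + tag + fwd_real[t.taxon_id]
            + t.amplicon_sequence + _revcomp(rev_real[t.taxon_id])
        )
        if config.per_base_error > 0:
            mat = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy().reshape(1, -1)
            _apply_substitutions(mat, config.per_base_error, rng)
            seq = mat.tobytes().decode("ascii")
        out.append(SimulatedRead(f"read{i:08d}", seq, QUALITY_CHAR * len(seq)))
    return out


# --------------------------------------------------------------------------
# Output


def write_fastq_and_truth(
    reads: Sequence[SimulatedRead],
    truth: SimulationTruth,
    output_prefix: Union[str, Path],
    config: Optional[SimulationConfig] = None,
) -> Dict[str, Path]:
    """Write FASTQ plus TSV truth tables and a JSON config echo.

    Files: ``<prefix>.fastq``, ``<prefix>.truth_taxa.tsv`` (per-taxon
    template counts and realized distinct-tag counts),
    ``<prefix>.truth_molecules.tsv`` (molecule -> tag map),
    ``<prefix>.truth_reads.tsv`` (read -> molecule provenance), and
    ``<prefix>.config.json`` when a config is supplied.
    """
    prefix = Path(output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}

    fastq = prefix.with_suffix(".fastq")
    with open(fastq, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
    paths["fastq"] = fastq

    taxa_tsv = Path(f"{prefix}.truth_taxa.tsv")
    with open(taxa_tsv, "w") as fh:
        fh.write("taxon_id\ttemplate_copies\tlabeled_molecules\th_true\n")
        for tt in truth.per_taxon.values():
            fh.write(f"{tt.taxon_id}\t{tt.template_copies}\t{tt.labeled_molecules}\t{tt.h_true}\n")
    paths["truth_taxa"] = taxa_tsv

    mol_tsv = Path(f"{prefix}.truth_molecules.tsv")
    with open(mol_tsv, "w") as fh:
        fh.write("taxon_id\tmolecule_index\ttag\n")
        for tt in truth.per_taxon.values():
            for i, tag in enumerate(tt.tags):
                fh.write(f"{tt.taxon_id}\t{i}\t{tag}\n")
    paths["truth_molecules"] = mol_tsv

    reads_tsv = Path(f"{prefix}.truth_reads.tsv")
    with open(reads_tsv, "w") as fh:
        fh.write("read_id\ttaxon_id\tmolecule_index\n")
        for read_id, taxon_id, mol in truth.provenance:
            fh.write(f"{read_id}\t{taxon_id}\t{mol}\n")
    paths["truth_reads"] = reads_tsv

    if config is not None:
        cfg_json = Path(f"{prefix}.config.json")
        with open(cfg_json, "w") as fh:
            json.dump(config.to_jsonable(), fh, indent=2)
            fh.write("\n")
        paths["config"] = cfg_json
    return paths
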