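"""Transcript-level consequence prediction for gene-inactivating variants.

This module reasons about what a variant does to a spliced coding sequence:
build the spliced transcript from an exon model, apply edits (deletions,
insertions, substitutions, exon skipping, splice-donor shifts, intron
retention), translate, find the last residue still matching the reference
protein, count the ectopic codons read in the shifted frame before the stop,
locate the stop relative to the exon-junction chain, predict
nonsense-mediated decay (NMD), and compute predicted protein sizes.

Conventions: genomic coordinates 1-based inclusive; transcript coordinates
1-based from the spliced transcript's first base, with the CDS anchored at
``cds_start``. Minus-strand genes are reverse-complemented at model load;
everything downstream is transcript-oriented. The default NMD rule flags any
stop codon 5' of the final exon-exon junction; the stricter literature rule
(>=50 nt upstream of the final junction) is an explicit mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import yaml
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "GeneModel", "Transcript", "TranscriptVariant", "ConsequenceReport",
    "Deletion", "Insertion", "Substitution", "ExonSkip", "DonorShift",
    "IntronRetention",
    "spliced_cds", "apply_variant", "analyze_orf", "predict_nmd",
    "protein_mw", "consequence", "inverse_variant",
    "read_gene_model", "read_variant", "read_fasta",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Average residue masses in daltons (standard 20 amino acids) plus one
#: water per chain; matches SDS-PAGE-style predicted molecular weights.
RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_DA = 18.0153


def protein_mw(sequence: str) -> float:
    """Average-mass molecular weight of a protein, in kilodaltons.

    Sum of average residue masses plus one water (18.02 Da). Strictly
    additive: ``mw(s1 + s2) == mw(s1) + mw(s2) - 0.0180153`` kDa.
    """
    if not sequence:
        raise ValueError("protein_mw: empty sequence")
    total = WATER_DA
    for aa in sequence:
        try:
            total += RESIDUE_MASS_DA[aa.upper()]
        except KeyError:
            raise ValueError(f"protein_mw: unknown residue code {aa!r}") from None
    return total / 1000.0


# ---------------------------------------------------------------------------
# Gene model and spliced transcript
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Exon model over an in-memory genome.

    ``exons`` are (start, end) pairs, 1-based inclusive genomic coordinates,
    listed 5'->3' in transcript orientation (descending genomic position on
    the minus strand). ``cds_start`` is the 1-based offset of the first CDS
    base within the spliced transcript.
    """

    name: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    genome: dict[str, str]
    cds_start: int = 1

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "exons",
                           tuple((int(s), int(e)) for s, e in self.exons))
        if self.contig not in self.genome:
            raise KeyError(f"contig {self.contig!r} not in genome")
        contig_len = len(self.genome[self.contig])
        prev = None
        for s, e in self.exons:
            if not (1 <= s <= e <= contig_len):
                raise ValueError(
                    f"exon {s}-{e} outside contig {self.contig!r} "
                    f"(length {contig_len})")
            key = s if self.strand == "+" else -s
            if prev is not None and key <= prev:
                raise ValueError("exons must be non-overlapping and ordered "
                                 "5'->3' in transcript orientation")
            prev = e if self.strand == "+" else -e
        if self.cds_start < 1:
            raise ValueError("cds_start must be >= 1")

    def exon_seq(self, i: int) -> str:
        """Transcript-oriented sequence of exon i (0-based index)."""
        s, e = self.exons[i]
        raw = self.genome[self.contig][s - 1:e]
        return raw.upper() if self.strand == "+" else \
            str(Seq(raw.upper()).reverse_complement())

    def intron_seq(self, i: int) -> str:
        """Transcript-oriented sequence of the intron after exon i."""
        if not (0 <= i < len(self.exons) - 1):
            raise IndexError(f"no intron after exon index {i}")
        a, b = self.exons[i], self.exons[i + 1]
        if self.strand == "+":
            raw = self.genome[self.contig][a[1]:b[0] - 1]
            return raw.upper()
        raw = self.genome[self.contig][b[1]:a[0] - 1]
        return str(Seq(raw.upper()).reverse_complement())


@dataclass
class Transcript:
    """Spliced transcript: sequence, junction positions and CDS anchor.

    ``junctions[k]`` is the transcript position (1-based) of the last base
    of exon k; an exon-exon junction lies between ``junctions[k]`` and
    ``junctions[k] + 1``. The final entry (the transcript end) is not a
    junction and is excluded from the list.
    """

    seq: str
    junctions: list[int]
    cds_start: int = 1
    model: GeneModel | None = None

    @property
    def cds(self) -> str:
        return self.seq[self.cds_start - 1:]

    def exon_of(self, pos: int) -> int:
        """1-based exon index containing transcript position ``pos``."""
        for k, j in enumerate(self.junctions):
            if pos <= j:
                return k + 1
        return len(self.junctions) + 1


def spliced_cds(model: GeneModel) -> Transcript:
    """Concatenate exons into the spliced transcript with junction list."""
    parts = [model.exon_seq(i) for i in range(len(model.exons))]
    seq = "".join(parts)
    if len(seq) - (model.cds_start - 1) < 3:
        raise ValueError("CDS shorter than one codon")
    junctions, pos = [], 0
    for p in parts[:-1]:
        pos += len(p)
        junctions.append(pos)
    return Transcript(seq=seq, junctions=junctions,
                      cds_start=model.cds_start, model=model)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Deletion:
    position: int  # transcript coordinate of first deleted base (1-based)
    length: int


@dataclass(frozen=True)
class Insertion:
    position: int  # inserted sequence goes before this transcript position
    sequence: str


@dataclass(frozen=True)
class Substitution:
    position: int
    base: str


@dataclass(frozen=True)
class ExonSkip:
    exons: tuple[int, ...]  # 1-based exon indices

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(int(e) for e in self.exons))


@dataclass(frozen=True)
class DonorShift:
    exon: int  # 1-based exon index whose donor site shifts
    offset: int  # >0: readthrough into the intron by this many nt


@dataclass(frozen=True)
class IntronRetention:
    intron: int  # 1-based index: intron k follows exon k


Edit = Deletion | Insertion | Substitution | ExonSkip | DonorShift | IntronRetention


@dataclass(frozen=True)
class TranscriptVariant:
    """Ordered edit list, positions in the pre-edit transcript frame."""

    edits: tuple[Edit, ...]

    def __post_init__(self):
        object.__setattr__(self, "edits", tuple(self.edits))


@dataclass(frozen=True)
class _Span:
    """An edit normalized to a replacement span on the pre-edit transcript.

    ``start..end`` (1-based inclusive) is replaced by ``repl``; ``end =
    start - 1`` encodes a pure insertion before ``start``. ``drop_junction``
    is the 0-based index of a junction this edit erases (intron retention);
    ``donor_junction`` is the pre-edit position of a junction that rides
    with a shifted donor site.
    """

    start: int
    end: int
    repl: str
    drop_junction: int | None = None
    donor_junction: int | None = None


def _edit_interval(edit: Edit, tx: Transcript) -> _Span:
    n = len(tx.seq)
    if isinstance(edit, Deletion):
        if edit.length < 1 or not (1 <= edit.position <= n - edit.length + 1):
            raise ValueError(f"deletion out of bounds: {edit}")
        return _Span(edit.position, edit.position + edit.length - 1, "")
    if isinstance(edit, Insertion):
        if not (1 <= edit.position <= n + 1):
            raise ValueError(f"insertion out of bounds: {edit}")
        return _Span(edit.position, edit.position - 1, edit.sequence.upper())
    if isinstance(edit, Substitution):
        if not (1 <= edit.position <= n):
            raise ValueError(f"substitution out of bounds: {edit}")
        return _Span(edit.position, edit.position, edit.base.upper())
    boundaries = [0] + list(tx.junctions) + [n]
    if isinstance(edit, ExonSkip):
        ex = sorted(edit.exons)
        if ex != list(range(ex[0], ex[-1] + 1)):
            raise ValueError("exon_skip indices must be contiguous")
        if not (1 <= ex[0] and ex[-1] <= len(boundaries) - 1):
            raise ValueError(f"exon index out of range: {edit}")
        return _Span(boundaries[ex[0] - 1] + 1, boundaries[ex[-1]], "")
    if isinstance(edit, DonorShift):
        if tx.model is None:
            raise ValueError("donor_shift requires a gene model (intron sequence)")
        k = edit.exon
        if not (1 <= k <= len(tx.junctions)):
            raise ValueError(f"exon {k} has no downstream donor site")
        j = boundaries[k]
        if edit.offset > 0:
            intron = tx.model.intron_seq(k - 1)
            if edit.offset > len(intron):
                raise ValueError(
                    f"donor shift {edit.offset}nt exceeds intron length "
                    f"{len(intron)}")
            return _Span(j + 1, j, intron[:edit.offset], donor_junction=j)
        if edit.offset < 0:
            exon_len = boundaries[k] - boundaries[k - 1]
            if -edit.offset >= exon_len:
                raise ValueError("donor shift removes the whole exon")
            return _Span(j + edit.offset + 1, j, "", donor_junction=j)
        raise ValueError("donor shift offset must be nonzero")
    if isinstance(edit, IntronRetention):
        if tx.model is None:
            raise ValueError("intron_retention requires a gene model")
        k = edit.intron
        if not (1 <= k <= len(tx.junctions)):
            raise ValueError(f"no intron {k}")
        j = boundaries[k]
        return _Span(j + 1, j, tx.model.intron_seq(k - 1), drop_junction=k - 1)
    raise TypeError(f"unknown edit type: {edit!r}")


def apply_variant(tx: Transcript, variant: TranscriptVariant) -> Transcript:
    """Apply all edits (positions refer to the pre-edit transcript).

    Edits may not overlap. Junction positions, the CDS anchor and the
    junction list are kept consistent: junctions inside a skipped span
    vanish, a retained intron erases its junction, and a shifted donor
    site's junction moves with the new exon end.
    """
    spans = [_edit_interval(e, tx) for e in variant.edits]
    order = sorted(range(len(spans)), key=lambda i: (spans[i].start, spans[i].end))
    for a, b in zip(order, order[1:]):
        if spans[b].start <= spans[a].end:
            raise ValueError(
                f"overlapping edits: {variant.edits[a]} and {variant.edits[b]}")
    dropped = {s.drop_junction for s in spans if s.drop_junction is not None}
    seq = tx.seq
    # (original_index, position); positions updated as edits apply
    junc = [(k, j) for k, j in enumerate(tx.junctions) if k not in dropped]
    cds_start = tx.cds_start
    for i in reversed(order):  # right-to-left keeps pre-edit coordinates valid
        s = spans[i]
        seq = seq[:s.start - 1] + s.repl + seq[s.end:]
        delta = len(s.repl) - (s.end - s.start + 1)
        new_j = []
        for k, j in junc:
            if s.donor_junction is not None and j == s.donor_junction:
                new_j.append((k, s.start - 1 + len(s.repl)))
            elif j < s.start:
                new_j.append((k, j))
            elif j <= s.end:  # junction inside a removed span (exon skip)
                continue
            else:
                new_j.append((k, j + delta))
        junc = new_j
        if cds_start > s.end:
            cds_start += delta
        elif s.start <= cds_start <= s.end and delta != 0:
            raise ValueError("length-changing edit spans the CDS start")
    junctions = sorted({j for _, j in junc})
    return Transcript(seq=seq, junctions=junctions, cds_start=cds_start,
                      model=tx.model)


def inverse_variant(tx: Transcript, variant: TranscriptVariant) -> TranscriptVariant:
    """Variant that undoes `variant` on ``apply_variant(tx, variant)``.

    Supported for deletions, insertions, substitutions and donor shifts
    (structural exon edits do not have a coordinate-stable inverse).
    """
    if len(variant.edits) != 1:
        raise ValueError("inverse_variant supports single-edit variants")
    edit = variant.edits[0]
    if isinstance(edit, Deletion):
        removed = tx.seq[edit.position - 1: edit.position - 1 + edit.length]
        return TranscriptVariant((Insertion(edit.position, removed),))
    if isinstance(edit, Insertion):
        return TranscriptVariant((Deletion(edit.position, len(edit.sequence)),))
    if isinstance(edit, Substitution):
        original = tx.seq[edit.position - 1]
        return TranscriptVariant((Substitution(edit.position, original),))
    if isinstance(edit, DonorShift):
        return TranscriptVariant((DonorShift(edit.exon, -edit.offset),))
    raise ValueError(f"no coordinate-stable inverse for {edit!r}")


# ---------------------------------------------------------------------------
# ORF analysis
# ---------------------------------------------------------------------------

_CODON_TABLE = None


def _translate_codon(codon: str) -> str:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE = dict(standard_dna_table.forward_table)
    if codon in STOP_CODONS:
        return "*"
    try:
        return _CODON_TABLE[codon]
    except KeyError:
        raise ValueError(f"cannot translate codon {codon!r}") from None


@dataclass
class ConsequenceReport:
    """Outcome of translating a (possibly edited) transcript.

    ``last_intact_residue`` is the length of the longest protein prefix
    matching the reference (``last_intact_label`` names it, e.g. "Ser532");
    ``ectopic_codon_count`` counts codons translated in the shifted frame
    strictly after that prefix and strictly before the stop (0 unless
    frameshifted). ``stop_position`` is the transcript coordinate of the
    stop codon's first base (absent for nonstop transcripts).
    """

    frameshift: bool
    last_intact_residue: int
    last_intact_label: str
    ectopic_codon_count: int
    stop_position: int | None
    ptc_exon_index: int | None
    nmd_predicted: bool
    nonstop: bool
    full_length: bool
    truncated_protein_length: int
    protein: str
    predicted_mw_kda: float
    intact_prefix_mw_kda: float | None
    nmd_mode: str = "any-exon"

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def predict_nmd(stop_position: int, junctions, mode: str = "any-exon") -> bool:
    """Is a stop at `stop_position` predicted to trigger NMD?

    ``any-exon`` (default): any stop 5' of the final exon-exon junction,
    i.e. in any exon before the terminal exon. ``50nt``: only stops at
    least 50 nt upstream of the final junction.
    """
    junctions = list(junctions)
    if not junctions:
        return False
    final = junctions[-1]
    if mode == "any-exon":
        return stop_position <= final
    if mode == "50nt":
        return final - stop_position >= 50
    raise ValueError(f"unknown NMD mode {mode!r}")


def analyze_orf(tx: Transcript, reference_protein: str,
                reference_cds_length: int | None = None,
                nmd_mode: str = "any-exon") -> ConsequenceReport:
    """Translate from the CDS anchor and report the ORF consequence.

    The frameshift flag is the frame arithmetic of the edit: it is set iff
    the CDS length changed by an amount not divisible by 3 (requires
    ``reference_cds_length``; defaults to unshifted when omitted).
    """
    cds = tx.cds.upper()
    protein_parts = []
    stop_position = None
    for i in range(0, len(cds) - 2, 3):
        aa = _translate_codon(cds[i:i + 3])
        if aa == "*":
            stop_position = tx.cds_start + i
            break
        protein_parts.append(aa)
    protein = "".join(protein_parts)
    nonstop = stop_position is None

    reference_protein = (reference_protein or "").upper()
    intact = 0
    for a, b in zip(protein, reference_protein):
        if a != b:
            break
        intact += 1
    if intact:
        label = f"{seq3(protein[intact - 1])}{intact}"
    else:
        label = "None0"

    if reference_cds_length is None:
        frameshift = False
    else:
        frameshift = (len(cds) - reference_cds_length) % 3 != 0
    ectopic = len(protein) - intact if frameshift else 0

    full_length = (not nonstop) and protein == reference_protein
    ptc_exon = tx.exon_of(stop_position) if stop_position is not None else None
    nmd = (predict_nmd(stop_position, tx.junctions, mode=nmd_mode)
           if stop_position is not None else False)
    return ConsequenceReport(
        frameshift=frameshift,
        last_intact_residue=intact,
        last_intact_label=label,
        ectopic_codon_count=ectopic,
        stop_position=stop_position,
        ptc_exon_index=ptc_exon,
        nmd_predicted=nmd,
        nonstop=nonstop,
        full_length=full_length,
        truncated_protein_length=len(protein),
        protein=protein,
        predicted_mw_kda=protein_mw(protein) if protein else 0.0,
        intact_prefix_mw_kda=(protein_mw(protein[:intact]) if intact else None),
        nmd_mode=nmd_mode)


def consequence(model: GeneModel, variant: TranscriptVariant,
                nmd_mode: str = "any-exon") -> ConsequenceReport:
    """End-to-end: splice, derive the reference protein, edit, analyze."""
    tx = spliced_cds(model)
    ref_report = analyze_orf(tx, "", reference_cds_length=None)
    reference_protein = ref_report.protein
    mutant = apply_variant(tx, variant)
    return analyze_orf(mutant, reference_protein,
                       reference_cds_length=len(tx.cds),
                       nmd_mode=nmd_mode)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence}."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_model(path, genome: dict[str, str]) -> GeneModel:
    """Read a gene model from YAML or GFF3.

    YAML schema: ``{name, contig, strand, cds_start, exons: [[start, end],
    ...]}`` with exons in transcript order. GFF3: ``exon`` features of one
    gene on one contig; exons are ordered by strand automatically.
    """
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return GeneModel(name=d["name"], contig=d["contig"],
                         strand=d["strand"],
                         exons=tuple(tuple(e) for e in d["exons"]),
                         cds_start=int(d.get("cds_start", 1)), genome=genome)
    # minimal GFF3: seqid source type start end score strand phase attrs
    exons, contig, strand, name = [], None, None, "gene"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8 or f[2].lower() != "exon":
                continue
            contig, strand = f[0], f[6]
            exons.append((int(f[3]), int(f[4])))
            if len(f) > 8 and "Parent=" in f[8]:
                name = f[8].split("Parent=")[1].split(";")[0]
    if not exons:
        raise ValueError(f"no exon features found in {path}")
    exons.sort(key=lambda se: se[0], reverse=(strand == "-"))
    return GeneModel(name=name, contig=contig, strand=strand,
                     exons=tuple(exons), genome=genome)


_EDIT_READERS = {
    "deletion": lambda d: Deletion(int(d["position"]), int(d["length"])),
    "insertion": lambda d: Insertion(int(d["position"]), str(d["sequence"])),
    "substitution": lambda d: Substitution(int(d["position"]), str(d["base"])),
    "exon_skip": lambda d: ExonSkip(tuple(d["exons"])),
    "donor_shift": lambda d: DonorShift(int(d["exon"]), int(d["offset"])),
    "intron_retention": lambda d: IntronRetention(int(d["intron"])),
}


def read_variant(path) -> TranscriptVariant:
    """Read a YAML variant spec: a list of ``{op: ..., ...}`` edits."""
    with open(path) as fh:
        items = yaml.safe_load(fh)
    edits = []
    for item in items:
        op = item.get("op")
        if op not in _EDIT_READERS:
            raise ValueError(f"unknown edit op {op!r}; "
                             f"known: {sorted(_EDIT_READERS)}")
        edits.append(_EDIT_READERS[op](item))
    return TranscriptVariant(tuple(edits))
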