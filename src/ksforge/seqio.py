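"""FASTA I/O, CDS/protein consistency checks, and input quality filters.

The pipeline starts from two FASTA files per species: coding sequences
(nucleotide) and their protein translations, with matching identifiers.
Before any downstream analysis the gene set is reduced to one clean record
per gene: the longest CDS isoform is retained, records with premature stop
codons or proteins shorter than ``min_aa`` residues are removed, and any
CDS whose translation disagrees with the supplied protein is dropped with
a warning.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
STOP_CODONS = frozenset(_CODON_TABLE.stop_codons)
CODON_TO_AA = dict(_CODON_TABLE.forward_table)


class FastaParseError(ValueError):
    """Raised when a FASTA file is syntactically malformed."""


class FrameError(ValueError):
    """Raised when a CDS length is not a multiple of three."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identifier, CDS (stop-trimmed) and its protein.

    Invariants (enforced by :func:`qc_filter`): the CDS length is a
    multiple of 3, its translation equals ``protein`` exactly, and the
    protein contains no internal stop symbol.
    """

    gene_id: str
    cds: str
    protein: str


@dataclass
class QcReport:
    n_input: int = 0
    n_kept: int = 0
    n_dropped_stop: int = 0
    n_dropped_short: int = 0
    n_dropped_mismatch: int = 0
    n_dropped_isoform: int = 0

    def to_tsv(self) -> str:
        fields = (
            "n_input n_kept n_dropped_stop n_dropped_short "
            "n_dropped_mismatch n_dropped_isoform".split()
        )
        header = "\t".join(fields)
        values = "\t".join(str(getattr(self, f)) for f in fields)
        return f"{header}\n{values}\n"


def open_text(path: str | Path, mode: str = "rt"):
    """Open a plain or gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into an ordered list of ``(id, sequence)`` pairs.

    The identifier is the first whitespace-delimited token of the header
    line; sequences are upper-cased. Raises :class:`FastaParseError` with
    the offending line number if sequence data precedes any header.
    """
    entries: list[tuple[str, str]] = []
    current_id: str | None = None
    chunks: list[str] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if current_id is not None:
                    entries.append((current_id, "".join(chunks).upper()))
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                current_id = header.split()[0]
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"{path}: sequence before any FASTA header at line {lineno}"
                    )
                chunks.append(line.strip())
    if current_id is not None:
        entries.append((current_id, "".join(chunks).upper()))
    return entries


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open_text(path, "wt") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    Codons containing ``N`` translate to ``X``; stop codons to ``*``.
    """
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not a multiple of 3")
    aa = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            aa.append("X")
        elif codon in STOP_CODONS:
            aa.append("*")
        else:
            try:
                aa.append(CODON_TO_AA[codon])
            except KeyError:
                raise ValueError(f"invalid codon {codon!r} at nt {i}") from None
    return "".join(aa)


def _trim_terminal_stop(cds: str, protein: str) -> tuple[str, str]:
    if len(cds) % 3 == 0 and len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    if protein.endswith("*"):
        protein = protein[:-1]
    return cds, protein


def pair_records(
    cds_entries: Sequence[tuple[str, str]],
    pep_entries: Sequence[tuple[str, str]],
) -> tuple[list[GeneRecord], int]:
    """Join CDS and protein entries on identifier.

    Entries present in only one of the two files are dropped with a
    warning; the count of such drops is returned alongside the records.
    Terminal stop codons are trimmed here.
    """
    pep_map = dict(pep_entries)
    if len(pep_map) != len(pep_entries):
        logger.warning("duplicate identifiers in protein FASTA; last entry wins")
    records: list[GeneRecord] = []
    n_unpaired = 0
    seen = set()
    for gene_id, cds in cds_entries:
        if gene_id in seen:
            logger.warning("duplicate CDS identifier %s; keeping first", gene_id)
            continue
        seen.add(gene_id)
        if gene_id not in pep_map:
            logger.warning("CDS %s has no protein entry; dropped", gene_id)
            n_unpaired += 1
            continue
        cds_t, pep_t = _trim_terminal_stop(cds, pep_map[gene_id])
        records.append(GeneRecord(gene_id, cds_t, pep_t))
    n_missing_cds = len(set(pep_map) - seen)
    if n_missing_cds:
        logger.warning("%d protein entries had no CDS; dropped", n_missing_cds)
    return records, n_unpaired + n_missing_cds


def qc_filter(
    records: Sequence[GeneRecord],
    isoform_map: Mapping[str, Sequence[str]] | None = None,
    min_aa: int = 50,
    n_unpaired: int = 0,
) -> tuple[list[GeneRecord], QcReport]:
    """Apply the input quality filters.

    Per record: translation/frame mismatches are dropped, records whose
    CDS contains a premature (internal) stop codon are dropped, and
    proteins shorter than ``min_aa`` residues are dropped. If an
    ``isoform_map`` (gene -> isoform record ids) is given, only the
    longest surviving CDS per gene is retained (ties broken by smallest
    isoform id); without a map every record is its own gene.

    ``n_unpaired`` feeds identifier-level CDS/protein mismatches (from
    :func:`pair_records`) into the report's mismatch count.
    """
    report = QcReport(n_input=len(records) + n_unpaired)
    report.n_dropped_mismatch += n_unpaired

    valid: list[GeneRecord] = []
    for rec in records:
        cds, protein = _trim_terminal_stop(rec.cds, rec.protein)
        if len(cds) % 3 != 0:
            report.n_dropped_mismatch += 1
            logger.warning("%s: CDS length not a multiple of 3; dropped", rec.gene_id)
            continue
        aa = translate_cds(cds)
        if "*" in aa:
            report.n_dropped_stop += 1
            continue
        if aa != protein:
            report.n_dropped_mismatch += 1
            logger.warning("%s: CDS translation disagrees with protein; dropped", rec.gene_id)
            continue
        if len(protein) < min_aa:
            report.n_dropped_short += 1
            continue
        valid.append(GeneRecord(rec.gene_id, cds, protein))

    if isoform_map is not None:
        iso_to_gene: dict[str, str] = {}
        for gene, isoforms in isoform_map.items():
            for iso in isoforms:
                iso_to_gene[iso] = gene
        best: dict[str, GeneRecord] = {}
        order: list[str] = []
        for rec in valid:
            gene = iso_to_gene.get(rec.gene_id, rec.gene_id)
            prev = best.get(gene)
            if prev is None:
                best[gene] = rec
                order.append(gene)
            elif len(rec.cds) > len(prev.cds) or (
                # longer CDS wins; on equal length the smaller isoform id wins
                len(rec.cds) == len(prev.cds)
                and rec.gene_id < prev.gene_id
            ):
                best[gene] = rec
        kept = [best[g] for g in order]
        report.n_dropped_isoform = len(valid) - len(kept)
        valid = kept

    report.n_kept = len(valid)
    return valid, report


def load_gene_records(
    cds_path: str | Path,
    pep_path: str | Path,
    isoform_map: Mapping[str, Sequence[str]] | None = None,
    min_aa: int = 50,
) -> tuple[list[GeneRecord], QcReport]:
    """Read CDS + protein FASTA and return QC-filtered gene records."""
    cds_entries = read_fasta(cds_path)
    pep_entries = read_fasta(pep_path)
    records, n_unpaired = pair_records(cds_entries, pep_entries)
    return qc_filter(records, isoform_map=isoform_map, min_aa=min_aa, n_unpaired=n_unpaired)
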