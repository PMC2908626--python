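"""Readers, writers and promoter extraction for the pipeline's standard inputs.

All genomic coordinates are 1-based inclusive (GFF3 convention).  Gene tables
are TSV (or GFF3), protein/genomic sequences FASTA, similarity comes as
BLAST outfmt-6 tabular output, operon co-transcription probabilities as a
3-column TSV, and the optional species tree as newick (used only to order
output rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Phylo, SeqIO

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: characters accepted in genomic sequence after sanitization
DNA_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize_dna(seq: str, context: str = "") -> str:
    """Uppercase and map ambiguity characters other than N to N (warned)."""
    seq = seq.upper()
    if set(seq) <= DNA_ALPHABET:
        return seq
    bad = sorted(set(seq) - DNA_ALPHABET)
    logger.warning("mapping ambiguity characters %s to N%s", bad,
                   f" in {context}" if context else "")
    return "".join(c if c in DNA_ALPHABET else "N" for c in seq)


@dataclass
class GeneRecord:
    """One annotated gene.

    ``start``/``end`` are 1-based inclusive with ``start <= end`` regardless
    of strand; ``rank`` is the 1-based position of the gene along its
    replicon when sorted by start coordinate.
    """

    gene_id: str
    species_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    rank: int | None = None
    protein_seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(
                f"gene {self.gene_id!r}: strand {self.strand!r} invalid; "
                f"allowed strand symbols are {list(VALID_STRANDS)}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id!r}: start {self.start} < 1")
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )


@dataclass
class PromoterSeq:
    """A promoter window upstream of a gene start.

    ``truncated`` is set when the window ran off the replicon boundary
    (including the degenerate case of an empty window).
    """

    gene_id: str
    sequence: str
    truncated: bool


@dataclass
class GenomeSet:
    """Ordered gene annotations plus replicon sequences for a set of species."""

    species: list[str] = field(default_factory=list)
    #: (species_id, replicon_id) -> uppercase ACGTN sequence
    replicons: dict[tuple[str, str], str] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("species list contains duplicates")

    def genes_of(self, species_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.species_id == species_id]

    def gene_species(self) -> dict[str, str]:
        return {g.gene_id: g.species_id for g in self.genes}

    def validate(self) -> None:
        """Check coordinate bounds against replicon lengths and id uniqueness."""
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            seen, dup = set(), set()
            for i in ids:
                (dup if i in seen else seen).add(i)
            raise ValueError(f"duplicate gene_ids: {sorted(dup)[:5]}")
        for g in self.genes:
            key = (g.species_id, g.replicon_id)
            if key in self.replicons and g.end > len(self.replicons[key]):
                raise ValueError(
                    f"gene {g.gene_id!r}: end {g.end} exceeds replicon "
                    f"{g.replicon_id!r} length {len(self.replicons[key])}"
                )

    def promoters(self, window: int = 300) -> dict[str, PromoterSeq]:
        """Extract the upstream promoter window for every gene."""
        out: dict[str, PromoterSeq] = {}
        for g in self.genes:
            seq = self.replicons[(g.species_id, g.replicon_id)]
            out[g.gene_id] = extract_promoter(g, seq, window=window)
        return out


def assign_ranks(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Assign per-replicon ranks by sorting on (replicon_id, start)."""
    genes = list(genes)
    by_replicon: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_replicon.setdefault((g.species_id, g.replicon_id), []).append(g)
    for members in by_replicon.values():
        members.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(members, start=1):
            g.rank = rank
    return genes


_GENE_TABLE_COLUMNS = ["species_id", "gene_id", "replicon_id", "start", "end", "strand"]


def read_gene_table(path: str | Path, species_id: str | None = None) -> list[GeneRecord]:
    """Read gene annotations from the canonical TSV or from GFF3.

    The TSV dialect has a header row with columns
    ``species_id, gene_id, replicon_id, start, end, strand``.  GFF3 input
    (detected by extension or the ``##gff-version`` pragma) ingests only rows
    of type ``gene`` or ``CDS`` and requires ``species_id`` to be supplied,
    since GFF3 carries no species column.  Ranks are assigned by sorting on
    (replicon, start).
    """
    path = Path(path)
    head = path.read_text().lstrip()[:32]
    if path.suffix.lower() in (".gff", ".gff3") or head.startswith("##gff-version"):
        return _read_gff3(path, species_id)

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} missing columns: {missing}")
    genes = []
    for idx, row in df.iterrows():
        try:
            genes.append(
                GeneRecord(
                    gene_id=row["gene_id"],
                    species_id=row["species_id"],
                    replicon_id=row["replicon_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {idx + 2}: {exc}") from exc
    _check_unique_ids(genes)
    return assign_ranks(genes)


_GFF3_TYPES = {"gene", "CDS"}


def _read_gff3(path: Path, species_id: str | None) -> list[GeneRecord]:
    if species_id is None:
        raise ValueError("GFF3 input requires an explicit species_id")
    genes: list[GeneRecord] = []
    skipped = 0
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in _GFF3_TYPES:
                skipped += 1
                continue
            gene_id = _gff3_attr_id(attrs) or f"{seqid}:{start}-{end}"
            if gene_id in seen_ids:
                # a gene row and its CDS child share the feature; keep the first
                continue
            seen_ids.add(gene_id)
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    species_id=species_id,
                    replicon_id=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                )
            )
    logger.info("GFF3 %s: ingested %d gene/CDS rows, skipped %d other rows",
                path, len(genes), skipped)
    return assign_ranks(genes)


def _gff3_attr_id(attrs: str) -> str | None:
    parsed = dict(
        kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
    )
    for key in ("ID", "locus_tag", "Name"):
        if key in parsed:
            return parsed[key]
    return None


def _check_unique_ids(genes: Sequence[GeneRecord]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in gene table")
        seen.add(g.gene_id)


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write the canonical TSV dialect (byte-stable round trip with the reader)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.species_id}\t{g.gene_id}\t{g.replicon_id}\t"
                f"{g.start}\t{g.end}\t{g.strand}\n"
            )


def extract_promoter(gene: GeneRecord, replicon_seq: str, window: int = 300) -> PromoterSeq:
    """Return the promoter window upstream of a gene's annotated start.

    For a ``+`` strand gene the window is ``replicon[start-window .. start-1]``;
    for ``-`` it is the reverse complement of ``replicon[end+1 .. end+window]``
    (1-based inclusive).  Windows are truncated at replicon boundaries; a gene
    flush against the boundary yields the empty-promoter sentinel with
    ``truncated=True``.
    """
    n = len(replicon_seq)
    if gene.end > n:
        raise ValueError(
            f"gene {gene.gene_id!r}: end {gene.end} beyond replicon length {n}"
        )
    if gene.strand == "+":
        lo = max(0, gene.start - 1 - window)
        seq = replicon_seq[lo:gene.start - 1]
        truncated = (gene.start - 1) < window
    else:
        seq = reverse_complement(replicon_seq[gene.end:gene.end + window])
        truncated = (n - gene.end) < window
    return PromoterSeq(gene_id=gene.gene_id, sequence=seq, truncated=truncated)


def read_fasta(path: str | Path, dna: bool = True) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} dict (DNA is sanitized)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        out[rec.id] = sanitize_dna(seq, context=rec.id) if dna else seq.upper()
    return out


def load_genome_set(
    gene_table: str | Path,
    genome_fasta: str | Path,
    protein_fasta: str | Path | None = None,
) -> GenomeSet:
    """Assemble a validated GenomeSet from a gene table plus sequence FASTAs.

    FASTA record ids in ``genome_fasta`` are replicon ids; the gene table
    supplies the replicon-to-species mapping.
    """
    genes = read_gene_table(gene_table)
    seqs = read_fasta(genome_fasta, dna=True)
    if protein_fasta is not None:
        prots = read_fasta(protein_fasta, dna=False)
        for g in genes:
            g.protein_seq = prots.get(g.gene_id)
    species: list[str] = []
    replicons: dict[tuple[str, str], str] = {}
    for g in genes:
        if g.species_id not in species:
            species.append(g.species_id)
        key = (g.species_id, g.replicon_id)
        if key not in replicons:
            if g.replicon_id not in seqs:
                raise ValueError(f"replicon {g.replicon_id!r} absent from FASTA")
            replicons[key] = seqs[g.replicon_id]
    gs = GenomeSet(species=species, replicons=replicons, genes=genes)
    gs.validate()
    return gs


_OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_similarity_table(path: str | Path, evalue_max: float = 1e-5) -> pd.DataFrame:
    """Read BLAST outfmt-6 hits, filter by E-value and deduplicate pairs.

    Rows with E-value above ``evalue_max`` are dropped.  Duplicate
    (query, subject) rows keep the maximum bit score (count logged).  Self
    hits are retained: they carry the self-scores required downstream for
    normalization; queries lacking a self hit are logged here and make
    normalization fail loudly later.

    Returns a DataFrame with columns ``query, subject, bitscore``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 12:
        raise ValueError(
            f"{path}: expected 12 BLAST outfmt-6 columns, got {df.shape[1]}"
        )
    df.columns = _OUTFMT6_COLUMNS
    df = df[df["evalue"] <= evalue_max]
    n_before = len(df)
    df = (
        df.groupby(["qseqid", "sseqid"], sort=False, as_index=False)["bitscore"]
        .max()
    )
    n_dups = n_before - len(df)
    if n_dups:
        logger.info("%s: collapsed %d duplicate (query,subject) rows (kept max bitscore)",
                    path, n_dups)
    df = df.rename(columns={"qseqid": "query", "sseqid": "subject"})
    queries = set(df["query"]) | set(df["subject"])
    with_self = set(df.loc[df["query"] == df["subject"], "query"])
    missing = queries - with_self
    if missing:
        logger.warning("%s: %d sequences have no self hit (normalization will fail "
                       "for them): e.g. %s", path, len(missing), sorted(missing)[:3])
    return df.reset_index(drop=True)


def read_operon_table(path: str | Path, genes: Sequence[GeneRecord]):
    """Read a VIMSS-style 3-column TSV of adjacent-pair co-transcription probabilities.

    Columns: ``gene_id_1, gene_id_2, p_cotranscribed``.  Pairs whose genes are
    not rank-adjacent on the same replicon are ignored with a warning;
    probabilities outside [0, 1] are a hard error.  Returns an
    :class:`~regulonkit.motif_scanning.OperonMap`.
    """
    from regulonkit.motif_scanning import OperonMap

    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns gene_id_1, gene_id_2, p_cotranscribed")
    df.columns = ["gene_id_1", "gene_id_2", "p_cotranscribed"] + list(df.columns[3:])
    by_id = {g.gene_id: g for g in genes}
    pairs: dict[tuple[str, str], float] = {}
    for idx, row in df.iterrows():
        p = float(row["p_cotranscribed"])
        if not 0.0 <= p <= 1.0:
            raise ValueError(
                f"{path} row {idx + 2}: p_cotranscribed {p} outside [0, 1]"
            )
        a = by_id.get(row["gene_id_1"])
        b = by_id.get(row["gene_id_2"])
        if a is None or b is None:
            logger.warning("%s row %d: unknown gene id; pair ignored", path, idx + 2)
            continue
        ok = (
            a.species_id == b.species_id
            and a.replicon_id == b.replicon_id
            and a.rank is not None and b.rank is not None
            and abs(a.rank - b.rank) == 1
        )
        if not ok:
            logger.warning(
                "%s row %d: genes %s and %s are not rank-adjacent on one "
                "replicon; pair ignored", path, idx + 2, a.gene_id, b.gene_id,
            )
            continue
        if a.strand != b.strand:
            logger.warning(
                "%s row %d: genes %s and %s are on opposite strands; pair "
                "ignored (cannot share a transcription unit)",
                path, idx + 2, a.gene_id, b.gene_id,
            )
            continue
        up, down = _transcription_order(a, b)
        if p > 0.0:
            pairs[(up.gene_id, down.gene_id)] = p
    return OperonMap(pairs=pairs)


def _transcription_order(a: GeneRecord, b: GeneRecord) -> tuple[GeneRecord, GeneRecord]:
    """Order a same-strand rank-adjacent pair as (upstream, downstream)."""
    first, second = (a, b) if a.rank < b.rank else (b, a)
    return (first, second) if a.strand == "+" else (second, first)


def read_aligned_sites(path: str | Path) -> list[str]:
    """Read aligned binding-site sequences (aligned FASTA, equal lengths)."""
    sites = [str(rec.seq).upper().replace("U", "T") for rec in SeqIO.parse(str(path), "fasta")]
    if not sites:
        raise ValueError(f"{path}: no sequences found")
    return sites


def read_newick_order(path: str | Path) -> list[str]:
    """Leaf names of a newick tree in tree (display) order, for output ordering."""
    tree = Phylo.read(str(path), "newick")
    return [leaf.name for leaf in tree.get_terminals()]
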