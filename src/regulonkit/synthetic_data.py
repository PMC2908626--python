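"""Synthetic genomes with planted regulons, for end-to-end testing.

The generator emulates the statistical structure the method assumes, at desk
scale: a set of species, a few regulators whose presence/absence profiles
overlap only partially, ortholog groups of target genes whose promoters carry
a planted binding site exactly where the generating regulator is present
(up to a configurable flip noise), operon structure that shares promoter
evidence downstream, and an all-vs-all protein similarity table whose
within-group bit scores dwarf between-group ones.  Everything is written in
the exact dialects :mod:`regulonkit.genome_io` reads, alongside a ground
truth for scoring recovery.

It does not attempt realistic sequence evolution: protein sequences are
consensus strings with i.i.d. mutations and promoters are i.i.d. background,
so passing tests demonstrate correctness of the inference machinery, not
robustness to real evolutionary heterogeneity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from regulonkit.genome_io import GeneRecord, GenomeSet, assign_ranks, reverse_complement, write_gene_table
from regulonkit.motif_scanning import BASES, OperonMap

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: canonical palindromic FNR-type binding site consensus
FNR_CONSENSUS = "TTGATNNNNATCAA"


def default_motif_counts(n_sites: int = 40) -> np.ndarray:
    """14-column count matrix consistent with the TTGAT-N4-ATCAA consensus.

    Informative columns put ``n_sites - 1`` counts on the consensus base and
    one on its complement; the 4 middle columns are uniform.  The matrix is
    exactly palindromic (equal to its own reverse complement).
    """
    counts = np.zeros((len(FNR_CONSENSUS), 4))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i, c in enumerate(FNR_CONSENSUS):
        if c == "N":
            counts[i] = n_sites / 4.0
        else:
            counts[i, BASES.index(c)] = n_sites - 1
            counts[i, BASES.index(comp[c])] = 1
    return counts


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults define the standard end-to-end recovery setting: 40 species,
    3 regulators with block-structured presence profiles of pairwise Jaccard
    <= 0.4, 30 target ortholog groups split round-robin across regulators,
    flip noise 0.1 on the (group, species) occurrence, and 400 background
    genes per species so that motif hits are rare, as per-species
    standardization assumes.
    """

    seed: int
    n_species: int = 40
    n_regulators: int = 3
    n_target_groups: int = 30
    n_background_genes: int = 400
    flip_noise: float = 0.1
    presence_model: str = "blocks"  # "blocks" or "tree"
    tree_gain_loss: float = 0.25
    gc_range: tuple[float, float] = (0.42, 0.58)
    motif_counts: np.ndarray = field(default_factory=default_motif_counts)
    n_aligned_sites: int = 40
    gene_length: int = 900
    promoter_window: int = 300
    operon_lead_prob: float = 0.3
    operon_geom_p: float = 0.5
    operon_max_extra: int = 3
    p_cotranscribed: float = 0.9
    operon_gap: int = 20
    unit_spacer: int = 60
    ortholog_loss: float = 0.0
    intra_bits: tuple[float, float] = (300.0, 400.0)
    inter_bits: tuple[float, float] = (40.0, 60.0)
    self_bits: tuple[float, float] = (400.0, 500.0)
    inter_edges_per_group: float = 2.0
    protein_length: int = 230
    protein_mutation_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("flip_noise", "operon_lead_prob", "operon_geom_p",
                     "p_cotranscribed", "ortholog_loss", "protein_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        self.motif_counts = np.asarray(self.motif_counts, dtype=float)
        w = self.motif_counts.shape[0]
        if self.promoter_window < w:
            raise ValueError(
                f"promoter window {self.promoter_window} shorter than motif ({w})"
            )
        if self.gene_length < 1 or self.operon_gap < 0 or self.unit_spacer < 0:
            raise ValueError("infeasible gene geometry")
        if self.presence_model not in ("blocks", "tree"):
            raise ValueError(f"unknown presence model {self.presence_model!r}")


@dataclass
class SimTruth:
    """Ground truth accompanying one simulated data set."""

    regulator_presence: pd.DataFrame  # regulators x species, bool
    occurrence: pd.DataFrame          # target groups x species, bool (planted sites)
    group_regulator: dict[str, str]   # target group -> generating regulator
    regulator_genes: dict[str, list[str]]
    target_group_genes: dict[str, list[str]]
    planted_offsets: dict[str, int]   # lead gene -> site offset within promoter
    operon_units: list[list[str]]
    partition: dict[str, str]         # gene -> true group label (incl. singletons)

    def to_dict(self) -> dict:
        return {
            "regulator_presence": {
                r: [bool(v) for v in row]
                for r, row in self.regulator_presence.iterrows()
            },
            "species": list(self.regulator_presence.columns),
            "occurrence": {
                g: [bool(v) for v in row] for g, row in self.occurrence.iterrows()
            },
            "group_regulator": self.group_regulator,
            "regulator_genes": self.regulator_genes,
            "target_group_genes": self.target_group_genes,
            "planted_offsets": self.planted_offsets,
            "operon_units": self.operon_units,
            "partition": self.partition,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        species = d["species"]
        return cls(
            regulator_presence=pd.DataFrame.from_dict(
                d["regulator_presence"], orient="index", columns=species
            ),
            occurrence=pd.DataFrame.from_dict(
                d["occurrence"], orient="index", columns=species
            ),
            group_regulator=d["group_regulator"],
            regulator_genes=d["regulator_genes"],
            target_group_genes=d["target_group_genes"],
            planted_offsets={k: int(v) for k, v in d["planted_offsets"].items()},
            operon_units=d["operon_units"],
            partition=d["partition"],
        )


@dataclass
class SimResult:
    """Simulated inputs (in memory) plus ground truth."""

    config: SimConfig
    genome_set: GenomeSet
    similarity: pd.DataFrame        # columns query, subject, bitscore, evalue
    operon_map: OperonMap
    operon_rows: list[tuple[str, str, float]]
    aligned_sites: list[str]
    truth: SimTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every input file in the dialects genome_io reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": out / "genes.tsv",
            "genomes": out / "genomes.fna",
            "proteins": out / "proteins.faa",
            "similarity": out / "similarity.tsv",
            "operons": out / "operons.tsv",
            "sites": out / "sites.afa",
            "truth": out / "truth.json",
        }
        write_gene_table(self.genome_set.genes, paths["genes"])
        with open(paths["genomes"], "w", newline="\n") as fh:
            for (_sp, rep), seq in self.genome_set.replicons.items():
                fh.write(f">{rep}\n{seq}\n")
        with open(paths["proteins"], "w", newline="\n") as fh:
            for g in self.genome_set.genes:
                if g.protein_seq:
                    fh.write(f">{g.gene_id}\n{g.protein_seq}\n")
        with open(paths["similarity"], "w", newline="\n") as fh:
            L = self.config.protein_length
            for row in self.similarity.itertuples(index=False):
                fh.write(
                    f"{row.query}\t{row.subject}\t90.0\t{L}\t0\t0\t1\t{L}\t1\t{L}\t"
                    f"{row.evalue:.1e}\t{row.bitscore:.1f}\n"
                )
        with open(paths["operons"], "w", newline="\n") as fh:
            fh.write("gene_id_1\tgene_id_2\tp_cotranscribed\n")
            for a, b, p in self.operon_rows:
                fh.write(f"{a}\t{b}\t{p:g}\n")
        with open(paths["sites"], "w", newline="\n") as fh:
            for i, s in enumerate(self.aligned_sites):
                fh.write(f">site_{i:03d}\n{s}\n")
        with open(paths["truth"], "w", newline="\n") as fh:
            json.dump(self.truth.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _block_presence(n_species: int, n_regulators: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Block-structured presence with wrap-around, through a seeded permutation.

    Blocks cover half the species each, with starts spaced so pairwise
    profile Jaccard stays modest (~0.1-0.25 for 3 regulators over 40 species).
    """
    width = max(2, round(0.5 * n_species))
    perm = rng.permutation(n_species)
    presence = np.zeros((n_regulators, n_species), dtype=bool)
    for r in range(n_regulators):
        start = round(r * 0.6 * n_species / max(n_regulators - 1, 1))
        idx = [(start + k) % n_species for k in range(width)]
        presence[r, perm[idx]] = True
    return presence


def _random_tree(leaves: list[int], rng: np.random.Generator):
    if len(leaves) == 1:
        return leaves[0]
    k = int(rng.integers(1, len(leaves)))
    return (_random_tree(leaves[:k], rng), _random_tree(leaves[k:], rng))


def _evolve(node, state: bool, mu: float, rng: np.random.Generator,
            out: dict[int, bool]) -> None:
    if isinstance(node, int):
        out[node] = state
        return
    for child in node:
        child_state = state ^ (rng.random() < mu)
        _evolve(child, child_state, mu, rng, out)


def _tree_presence(n_species: int, n_regulators: int, mu: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Presence by gain/loss along a random bifurcating species tree."""
    tree = _random_tree(list(range(n_species)), rng)
    presence = np.zeros((n_regulators, n_species), dtype=bool)
    for r in range(n_regulators):
        for _ in range(50):
            states: dict[int, bool] = {}
            _evolve(tree, True, mu, rng, states)
            vec = np.array([states[i] for i in range(n_species)])
            if 2 <= vec.sum() <= n_species - 1:
                presence[r] = vec
                break
        else:
            raise RuntimeError("could not draw a non-degenerate presence profile")
    return presence


def _rand_dna(n: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    idx = rng.choice(4, size=n, p=probs)
    return "".join(np.array(list(BASES))[idx]) if n < 64 else \
        np.frombuffer(np.array([ord(b) for b in BASES], dtype=np.uint8)[idx].tobytes(),
                      dtype=np.uint8).tobytes().decode("ascii")


def _sample_site(counts: np.ndarray, rng: np.random.Generator) -> str:
    n = counts.sum(axis=1)
    return "".join(
        BASES[rng.choice(4, p=counts[i] / n[i])] for i in range(counts.shape[0])
    )


def _mutate_protein(consensus: np.ndarray, rate: float,
                    rng: np.random.Generator) -> str:
    seq = consensus.copy()
    hit = rng.random(len(seq)) < rate
    if hit.any():
        seq[hit] = rng.integers(0, len(AMINO_ACIDS), size=int(hit.sum()))
    return "".join(AMINO_ACIDS[i] for i in seq)


def simulate(config: SimConfig) -> SimResult:
    """Generate one synthetic data set under the given study conditions.

    Deterministic in the seed: identical configs give byte-identical files.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    species = [f"SP{i + 1:02d}" for i in range(cfg.n_species)]
    regulators = [f"REG{r + 1}" for r in range(cfg.n_regulators)]
    target_groups = [f"TG{g + 1:03d}" for g in range(cfg.n_target_groups)]
    group_regulator = {
        g: regulators[i % cfg.n_regulators] for i, g in enumerate(target_groups)
    }
    w = cfg.motif_counts.shape[0]

    if cfg.presence_model == "blocks":
        presence = _block_presence(cfg.n_species, cfg.n_regulators, rng)
    else:
        presence = _tree_presence(cfg.n_species, cfg.n_regulators,
                                  cfg.tree_gain_loss, rng)
    presence_df = pd.DataFrame(presence, index=regulators, columns=species)

    # flip noise at the (group, species) level
    occurrence = np.zeros((cfg.n_target_groups, cfg.n_species), dtype=bool)
    for gi, g in enumerate(target_groups):
        r = regulators.index(group_regulator[g])
        flips = rng.random(cfg.n_species) < cfg.flip_noise
        occurrence[gi] = presence[r] ^ flips
    occurrence_df = pd.DataFrame(occurrence, index=target_groups, columns=species)

    # which species carry an ortholog of each target group
    has_ortholog = rng.random((cfg.n_target_groups, cfg.n_species)) >= cfg.ortholog_loss

    genes: list[GeneRecord] = []
    replicons: dict[tuple[str, str], str] = {}
    planted_offsets: dict[str, int] = {}
    operon_rows: list[tuple[str, str, float]] = []
    operon_units: list[list[str]] = []
    partition: dict[str, str] = {}
    regulator_genes: dict[str, list[str]] = {r: [] for r in regulators}
    target_group_genes: dict[str, list[str]] = {g: [] for g in target_groups}

    for si, sp in enumerate(species):
        gc = rng.uniform(*cfg.gc_range)
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        units: list[tuple[list[str], bool]] = []  # (gene ids in transcription order, plant?)
        for r in regulators:
            if presence_df.loc[r, sp]:
                gid = f"{r}__{sp}"
                regulator_genes[r].append(gid)
                partition[gid] = r
                units.append(([gid], False))
        for gi, g in enumerate(target_groups):
            if not has_ortholog[gi, si]:
                continue
            gid = f"{g}__{sp}"
            target_group_genes[g].append(gid)
            partition[gid] = g
            chain = [gid]
            if rng.random() < cfg.operon_lead_prob:
                extra = min(int(rng.geometric(cfg.operon_geom_p)), cfg.operon_max_extra)
                for k in range(extra):
                    fid = f"OP{g}_{k + 1}__{sp}"
                    partition[fid] = fid
                    chain.append(fid)
            units.append((chain, bool(occurrence[gi, si])))
        for k in range(cfg.n_background_genes):
            gid = f"BG{k + 1:04d}__{sp}"
            partition[gid] = gid
            units.append(([gid], False))
        order = rng.permutation(len(units))

        segments: list[str] = []
        cursor = 0
        replicon_id = f"{sp}_chr"
        for ui in order:
            chain, plant = units[ui]
            strand = "+" if rng.random() < 0.5 else "-"
            spacer = _rand_dna(cfg.unit_spacer, probs, rng)
            segments.append(spacer)
            cursor += len(spacer)
            promoter = _rand_dna(cfg.promoter_window, probs, rng)
            if plant:
                off = int(rng.integers(0, cfg.promoter_window - w + 1))
                site = _sample_site(cfg.motif_counts, rng)
                promoter = promoter[:off] + site + promoter[off + w:]
                planted_offsets[chain[0]] = off
            coords: list[tuple[int, int]] = []
            if strand == "+":
                segments.append(promoter)
                cursor += cfg.promoter_window
                for i, gid in enumerate(chain):
                    if i:
                        gap = _rand_dna(cfg.operon_gap, probs, rng)
                        segments.append(gap)
                        cursor += cfg.operon_gap
                    body = _rand_dna(cfg.gene_length, probs, rng)
                    segments.append(body)
                    coords.append((cursor + 1, cursor + cfg.gene_length))
                    cursor += cfg.gene_length
            else:
                for i, gid in enumerate(reversed(chain)):
                    if i:
                        gap = _rand_dna(cfg.operon_gap, probs, rng)
                        segments.append(gap)
                        cursor += cfg.operon_gap
                    body = _rand_dna(cfg.gene_length, probs, rng)
                    segments.append(body)
                    coords.append((cursor + 1, cursor + cfg.gene_length))
                    cursor += cfg.gene_length
                coords.reverse()  # align with transcription order of `chain`
                segments.append(reverse_complement(promoter))
                cursor += cfg.promoter_window
            for gid, (start, end) in zip(chain, coords):
                genes.append(GeneRecord(
                    gene_id=gid, species_id=sp, replicon_id=replicon_id,
                    start=start, end=end, strand=strand,
                ))
            if len(chain) > 1:
                operon_units.append(list(chain))
                for a, b in zip(chain, chain[1:]):
                    operon_rows.append((a, b, cfg.p_cotranscribed))
        replicons[(sp, replicon_id)] = "".join(segments)

    genes = assign_ranks(genes)
    genome_set = GenomeSet(species=list(species), replicons=replicons, genes=genes)
    genome_set.validate()

    # protein sequences: family consensus + i.i.d. mutations; background random
    family_consensus = {
        fam: rng.integers(0, len(AMINO_ACIDS), size=cfg.protein_length)
        for fam in regulators + target_groups
    }
    for g in genome_set.genes:
        fam = partition[g.gene_id]
        if fam in family_consensus:
            g.protein_seq = _mutate_protein(
                family_consensus[fam], cfg.protein_mutation_rate, rng
            )
        else:
            codes = rng.integers(0, len(AMINO_ACIDS), size=cfg.protein_length)
            g.protein_seq = "".join(AMINO_ACIDS[i] for i in codes)

    # similarity: strong within families, weak sampled noise between them
    rows: list[tuple[str, str, float, float]] = []
    all_ids = [g.gene_id for g in genome_set.genes]
    for gid in all_ids:
        rows.append((gid, gid, float(rng.uniform(*cfg.self_bits)), 1e-100))
    family_members = {
        fam: [g for g in all_ids if partition[g] == fam]
        for fam in regulators + target_groups
    }
    for fam in regulators + target_groups:
        members = family_members[fam]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                rows.append((members[i], members[j],
                             float(rng.uniform(*cfg.intra_bits)), 1e-60))
    # spurious cross-family hits are drawn between species only: the design
    # has no paralogs, so within-species similarity is limited to self-hits
    # (a lone within-species edge would hit the degenerate rescaling divisor)
    fam_list = regulators + target_groups
    gene_sp = {g.gene_id: g.species_id for g in genome_set.genes}
    n_inter = int(round(cfg.inter_edges_per_group * len(fam_list)))
    for _ in range(n_inter):
        fa, fb = rng.choice(len(fam_list), size=2, replace=False)
        a = family_members[fam_list[fa]]
        b = family_members[fam_list[fb]]
        if not a or not b:
            continue
        ga = a[int(rng.integers(len(a)))]
        gb = b[int(rng.integers(len(b)))]
        if gene_sp[ga] == gene_sp[gb]:
            continue
        rows.append((ga, gb, float(rng.uniform(*cfg.inter_bits)), 1e-6))
    similarity = pd.DataFrame(rows, columns=["query", "subject", "bitscore", "evalue"])

    aligned_sites = [_sample_site(cfg.motif_counts, rng)
                     for _ in range(cfg.n_aligned_sites)]

    pairs = {}
    for a, b, p in operon_rows:
        if p > 0:
            pairs[(a, b)] = p
    operon_map = OperonMap(pairs=pairs)

    truth = SimTruth(
        regulator_presence=presence_df,
        occurrence=occurrence_df,
        group_regulator=group_regulator,
        regulator_genes=regulator_genes,
        target_group_genes=target_group_genes,
        planted_offsets=planted_offsets,
        operon_units=operon_units,
        partition=partition,
    )
    return SimResult(
        config=cfg,
        genome_set=genome_set,
        similarity=similarity,
        operon_map=operon_map,
        operon_rows=operon_rows,
        aligned_sites=aligned_sites,
        truth=truth,
    )


@dataclass
class RecoveryMetrics:
    """How well a pipeline run recovered the planted structure."""

    rand_index: float
    site_recall: float
    site_precision: float
    assignment_fraction: float
    n_target_groups: int
    confusion: pd.DataFrame  # true regulator x assigned label


def score_recovery(
    truth: SimTruth,
    clusters: Mapping[str, Sequence[str]],
    scores: pd.DataFrame,
    assignments: Sequence,
    z_threshold: float = 3.0,
) -> RecoveryMetrics:
    """Score pipeline outputs against the simulation truth.

    ``clusters`` is the recovered ortholog partition (group id -> members),
    ``scores`` the per-gene score table with ``z`` (pre-propagation), and
    ``assignments`` the list of RegulonAssignment.  Each true target group is
    mapped to the recovered cluster holding the plurality of its members;
    the assignment fraction is the share of true groups whose mapped cluster
    was assigned to the generating regulator.
    """
    from sklearn.metrics import rand_score

    gene_cluster: dict[str, str] = {}
    for cid, members in clusters.items():
        for g in members:
            gene_cluster[g] = cid
    common = [g for g in truth.partition if g in gene_cluster]
    if not common:
        raise ValueError("no genes shared between truth and recovered partition")
    rand = float(rand_score(
        pd.factorize(np.asarray([truth.partition[g] for g in common]))[0],
        pd.factorize(np.asarray([gene_cluster[g] for g in common]))[0],
    ))

    z = dict(zip(scores["gene_id"], scores["z"]))
    planted = list(truth.planted_offsets)
    recall = (
        float(np.mean([z.get(g, float("-inf")) >= z_threshold for g in planted]))
        if planted else float("nan")
    )
    hits = [g for g, v in z.items() if v >= z_threshold]
    precision = (
        float(np.mean([g in truth.planted_offsets for g in hits]))
        if hits else float("nan")
    )

    by_group = {a.group_id: a for a in assignments}
    n_correct = 0
    records = []
    for g, members in truth.target_group_genes.items():
        counts: dict[str, int] = {}
        for m in members:
            cid = gene_cluster.get(m)
            if cid is not None:
                counts[cid] = counts.get(cid, 0) + 1
        assigned = "UNASSIGNED"
        if counts:
            mapped = max(sorted(counts), key=counts.get)
            if mapped in by_group:
                assigned = by_group[mapped].regulator
        true_reg = truth.group_regulator[g]
        records.append((true_reg, assigned))
        if assigned == true_reg:
            n_correct += 1
    confusion = (
        pd.DataFrame(records, columns=["true", "assigned"])
        .groupby(["true", "assigned"]).size().unstack(fill_value=0)
    )
    return RecoveryMetrics(
        rand_index=rand,
        site_recall=recall,
        site_precision=precision,
        assignment_fraction=n_correct / max(len(truth.target_group_genes), 1),
        n_target_groups=len(truth.target_group_genes),
        confusion=confusion,
    )
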