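"""Log-odds motif model, promoter scanning, per-species standardization,
empirical FDR, and operon-aware score propagation.

The binding-site model is an ungapped position weight matrix (log-odds in
bits against a background base composition) built from aligned sites.  Every
promoter is scored on both strands at every offset and keeps its single best
window.  Because background base composition varies across organisms, raw
scores are standardized per species (z-scores); z >= 3.0 is called
significant.  Promoter evidence at the first gene of a transcription unit is
propagated downstream: a gene's propagated score is the maximum of its own
score and the upstream gene's propagated score times the probability that the
two genes are co-transcribed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from regulonkit.genome_io import GeneRecord, PromoterSeq, reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = np.full(256, 4, dtype=np.int8)  # everything unknown -> N slot
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

#: default significance threshold on the per-species z scale
Z_THRESHOLD = 3.0


def _encode(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class MotifModel:
    """Ungapped log-odds matrix over a fixed motif width.

    ``counts`` is the (width, 4) base-count matrix of the aligned sites,
    ``background`` the background base frequencies (sums to 1), and
    ``log_odds`` the (width, 4) scoring matrix in bits:

        log_odds[i, b] = log2( (counts[i, b] + pc * bg[b]) / (n + pc) / bg[b] )

    with pseudocount ``pc`` and site count ``n``.  ``N`` in a scanned
    sequence contributes 0 (the background expectation).
    """

    counts: np.ndarray
    background: np.ndarray
    pseudocount: float
    n_sites: float
    log_odds: np.ndarray = field(init=False, repr=False)
    _lo_padded: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be a (width, 4) matrix")
        if self.width < 4:
            raise ValueError(f"motif width {self.width} < 4")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        with np.errstate(divide="ignore"):
            p = (self.counts + self.pseudocount * self.background) / (
                self.n_sites + self.pseudocount
            )
            self.log_odds = np.log2(p / self.background)
        self._lo_padded = np.zeros((self.width, 5))
        self._lo_padded[:, :4] = self.log_odds

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def probabilities(self) -> np.ndarray:
        """Pseudocount-smoothed per-column base probabilities."""
        return (self.counts + self.pseudocount * self.background) / (
            self.n_sites + self.pseudocount
        )

    def information_bits(self) -> float:
        """Total information content (KL from background) in bits."""
        p = self.probabilities()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / self.background), 0.0)
        return float(terms.sum())

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(
            counts=self.counts[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            n_sites=self.n_sites,
        )

    def is_palindromic(self, tol: float = 1e-9) -> bool:
        """True if the count matrix equals its own reverse complement."""
        return bool(
            np.allclose(self.counts, self.counts[::-1, ::-1], atol=tol)
            and np.allclose(self.background, self.background[::-1], atol=tol)
        )

    def score_window(self, window: str) -> float:
        """Log-odds score of a single window of exactly the motif width."""
        if len(window) != self.width:
            raise ValueError("window length must equal motif width")
        codes = _encode(window)
        return float(self._lo_padded[np.arange(self.width), codes].sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    def to_meme(self, name: str = "motif") -> str:
        """MEME minimal-format text for the letter-probability matrix."""
        p = self.probabilities()
        lines = [
            "MEME version 4", "",
            "ALPHABET= ACGT", "",
            "Background letter frequencies",
            " ".join(f"{b} {f:.4f}" for b, f in zip(BASES, self.background)), "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width} "
            f"nsites= {self.n_sites:g}",
        ]
        for row in p:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
        return "\n".join(lines)


def build_motif_model(
    aligned_sites: Sequence[str],
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
) -> MotifModel:
    """Build the log-odds model from aligned, equal-length binding sites.

    ``N`` characters contribute fractional background-weighted counts so each
    column still sums to the number of sites; a column of all N is an error.
    """
    sites = [s.upper() for s in aligned_sites]
    if len(sites) < 2:
        raise ValueError("need at least 2 aligned sites")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("aligned sites must all have equal length")
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    counts = np.zeros((w, 4))
    n_count = np.zeros(w)
    for s in sites:
        codes = _encode(s)
        for i, c in enumerate(codes):
            if c < 4:
                counts[i, c] += 1.0
            else:
                counts[i] += bg
                n_count[i] += 1
    if (n_count == len(sites)).any():
        bad = int(np.argmax(n_count == len(sites)))
        raise ValueError(f"motif column {bad} contains only N")
    return MotifModel(counts=counts, background=bg,
                      pseudocount=pseudocount, n_sites=len(sites))


def counts_from_consensus(consensus: str, n_sites: int = 20) -> np.ndarray:
    """Count matrix for a consensus string; IUPAC ``N`` columns are uniform."""
    consensus = consensus.upper()
    counts = np.zeros((len(consensus), 4))
    for i, c in enumerate(consensus):
        if c == "N":
            counts[i] = n_sites / 4.0
        elif c in BASES:
            counts[i, BASES.index(c)] = n_sites
        else:
            raise ValueError(f"consensus character {c!r} unsupported (use ACGTN)")
    return counts


@dataclass
class PromoterScore:
    """Best motif hit of one promoter plus its standardized scores.

    ``raw_score`` is the maximum summed log-odds over all offsets and both
    strands; promoters shorter than the motif carry the ``-inf`` sentinel.
    ``significant`` reflects the final (propagated) z against the threshold.
    """

    gene_id: str
    raw_score: float
    best_offset: int | None
    best_strand: str | None
    z_score: float | None = None
    significant: bool | None = None
    propagated_z: float | None = None


def _batch_raw_scores(
    codes: np.ndarray, model: MotifModel, both_strands: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best (score, offset, strand_code) per row of an encoded batch."""
    n, length = codes.shape
    w = model.width
    k = length - w + 1
    fwd = np.zeros((n, k))
    lo = model._lo_padded
    for j in range(w):
        fwd += lo[j][codes[:, j:j + k]]
    f_best = fwd.max(axis=1)
    f_off = fwd.argmax(axis=1)
    if not both_strands:
        return f_best, f_off, np.zeros(n, dtype=np.int8)
    rev = np.zeros((n, k))
    lo_rc = model.reverse_complement()._lo_padded
    for j in range(w):
        rev += lo_rc[j][codes[:, j:j + k]]
    r_best = rev.max(axis=1)
    r_off = rev.argmax(axis=1)
    # ties: smallest offset wins; at equal offset the forward strand wins
    use_fwd = (f_best > r_best) | ((f_best == r_best) & (f_off <= r_off))
    best = np.where(use_fwd, f_best, r_best)
    off = np.where(use_fwd, f_off, r_off)
    return best, off, np.where(use_fwd, 0, 1).astype(np.int8)


def scan_promoter(
    promoter: "str | PromoterSeq",
    model: MotifModel,
    both_strands: bool = True,
) -> PromoterScore:
    """Score one promoter; see :func:`scan_promoters` for the batch version.

    The raw score is the max summed log-odds over offsets ``0..L-w`` and both
    orientations; ties break to the smallest offset, forward strand first.  A
    promoter shorter than the motif returns the ``-inf`` sentinel (the gene
    is still carried through downstream with z = -inf).
    """
    gene_id = promoter.gene_id if isinstance(promoter, PromoterSeq) else ""
    seq = promoter.sequence if isinstance(promoter, PromoterSeq) else promoter
    if len(seq) < model.width:
        return PromoterScore(gene_id, float("-inf"), None, None)
    codes = _encode(seq)[None, :]
    best, off, strand = _batch_raw_scores(codes, model, both_strands)
    return PromoterScore(
        gene_id=gene_id,
        raw_score=float(best[0]),
        best_offset=int(off[0]),
        best_strand="+" if strand[0] == 0 else "-",
    )


def scan_promoters(
    promoters: Mapping[str, "str | PromoterSeq"],
    model: MotifModel,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Score many promoters (vectorized, bucketed by length).

    Returns a DataFrame with columns ``gene_id, raw_score, best_offset,
    best_strand`` in the input order; too-short promoters get the sentinel.
    """
    seqs = {
        g: (p.sequence if isinstance(p, PromoterSeq) else p)
        for g, p in promoters.items()
    }
    order = list(seqs)
    raw = pd.Series(float("-inf"), index=order)
    offs = pd.Series(pd.NA, index=order, dtype="Int64")
    strands = pd.Series(pd.NA, index=order, dtype="string")
    buckets: dict[int, list[str]] = {}
    for g, s in seqs.items():
        if len(s) >= model.width:
            buckets.setdefault(len(s), []).append(g)
    for length, genes in buckets.items():
        codes = np.vstack([_encode(seqs[g]) for g in genes])
        best, off, strand = _batch_raw_scores(codes, model, both_strands)
        raw[genes] = best
        offs[genes] = off
        strands[genes] = np.where(strand == 0, "+", "-")
    return pd.DataFrame(
        {
            "gene_id": order,
            "raw_score": raw.to_numpy(),
            "best_offset": offs.to_numpy(),
            "best_strand": strands.to_numpy(),
        }
    )


def standardize_per_species(
    scores: pd.DataFrame,
    z_threshold: float = Z_THRESHOLD,
    ddof: int = 0,
) -> pd.DataFrame:
    """Convert raw scores to per-species z-scores and flag significance.

    ``scores`` needs columns ``species_id`` and ``raw_score``.  Genes with
    the ``-inf`` sentinel are excluded from each species' mean/sd (population
    sd by default, ``ddof=0``) and receive z = -inf.  A species with zero
    score spread gets all z = 0 and no significant calls (warned).  Adds
    columns ``z`` and ``significant`` (z >= ``z_threshold``).
    """
    out = scores.copy()
    out["z"] = float("-inf")
    for species, grp in out.groupby("species_id"):
        finite = np.isfinite(grp["raw_score"].to_numpy(dtype=float))
        vals = grp["raw_score"].to_numpy(dtype=float)[finite]
        if len(vals) < 2:
            raise ValueError(
                f"species {species!r} has {len(vals)} finite scores; "
                "need at least 2 to standardize"
            )
        sd = float(np.std(vals, ddof=ddof))
        if sd == 0.0:
            logger.warning("species %s: zero score spread; all z set to 0", species)
            z = np.zeros(len(vals))
        else:
            z = (vals - vals.mean()) / sd
        idx = grp.index[finite]
        out.loc[idx, "z"] = z
    out["significant"] = out["z"] >= z_threshold
    return out


@dataclass
class OperonMap:
    """Adjacent-pair co-transcription probabilities and derived units.

    ``pairs`` maps (upstream_gene, downstream_gene) in transcription order to
    the probability the two genes are co-transcribed; only rank-adjacent
    same-strand pairs with p > 0 are stored.  Transcription units are the
    maximal chains of linked pairs.
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), p in self.pairs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pair ({a}, {b}): probability {p} outside [0, 1]")

    def successor(self) -> dict[str, tuple[str, float]]:
        succ: dict[str, tuple[str, float]] = {}
        for (a, b), p in self.pairs.items():
            if a in succ:
                raise ValueError(f"gene {a} has two downstream partners")
            succ[a] = (b, p)
        return succ

    def units(self) -> list[list[str]]:
        """Maximal co-transcription chains, each in transcription order."""
        succ = self.successor()
        downstreams = {b for (_, b) in self.pairs}
        heads = [a for a in succ if a not in downstreams]
        units = []
        for head in heads:
            chain = [head]
            g = head
            while g in succ:
                g = succ[g][0]
                if g in chain:
                    raise ValueError(f"cyclic operon chain at gene {g}")
                chain.append(g)
            units.append(chain)
        return units


def predict_operons_fallback(
    genes: Iterable[GeneRecord], max_gap: int = 50
) -> OperonMap:
    """Distance-based operon prediction when no co-transcription table exists.

    Rank-adjacent genes on the same replicon and strand with an intergenic
    gap of at most ``max_gap`` bp are co-transcribed with probability 1;
    every other pair gets 0 (and is not stored).
    """
    by_replicon: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_replicon.setdefault((g.species_id, g.replicon_id), []).append(g)
    pairs: dict[tuple[str, str], float] = {}
    for members in by_replicon.values():
        members = sorted(members, key=lambda g: g.rank)
        for prev, nxt in zip(members, members[1:]):
            if prev.strand != nxt.strand:
                continue
            gap = nxt.start - prev.end - 1
            if gap > max_gap:
                continue
            up, down = (prev, nxt) if prev.strand == "+" else (nxt, prev)
            pairs[(up.gene_id, down.gene_id)] = 1.0
    return OperonMap(pairs=pairs)


def propagate_operon_scores(
    z: Mapping[str, float], operon_map: OperonMap
) -> dict[str, float]:
    """Propagate z-scores down transcription units.

    Along each unit in transcription order, the first gene keeps its score
    and every downstream gene takes

        prop(g_i) = max(z(g_i), prop(g_{i-1}) * p(g_{i-1}, g_i)).

    Propagation never flows upstream.  Genes outside any unit keep their own
    score.  The operation is idempotent and never decreases a gene's score.
    """
    prop = dict(z)
    succ = operon_map.successor()
    for unit in operon_map.units():
        for up, down in zip(unit, unit[1:]):
            p = succ[up][1]
            up_score = prop.get(up, float("-inf"))
            if down in prop:
                prop[down] = max(prop[down], up_score * p)
    return prop


def propagate_scores_df(
    scores: pd.DataFrame,
    operon_map: OperonMap,
    z_threshold: float = Z_THRESHOLD,
) -> pd.DataFrame:
    """DataFrame wrapper: adds ``propagated_z`` and re-evaluates ``significant``."""
    z = dict(zip(scores["gene_id"], scores["z"]))
    prop = propagate_operon_scores(z, operon_map)
    out = scores.copy()
    out["propagated_z"] = out["gene_id"].map(prop)
    out["significant"] = out["propagated_z"] >= z_threshold
    return out


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Composition-preserving random permutation of a sequence."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return arr.tobytes().decode("ascii")


def dinucleotide_shuffle(
    seq: str, rng: np.random.Generator, max_tries: int = 1000
) -> str:
    """Dinucleotide-composition-preserving shuffle (random Eulerian walk).

    The sequence is viewed as an Eulerian path on the dinucleotide multigraph;
    out-edge lists are permuted until a permutation admits a complete walk.
    Falls back to a mononucleotide shuffle (warned) if none is found within
    ``max_tries`` — in practice only for degenerate inputs.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(seq) - 1
    for _ in range(max_tries):
        pools = {a: list(rng.permutation(bs)) for a, bs in edges.items()}
        pos = {a: 0 for a in pools}
        walk = [seq[0]]
        cur = seq[0]
        while pos.get(cur, 0) < len(pools.get(cur, [])):
            nxt = pools[cur][pos[cur]]
            pos[cur] += 1
            walk.append(nxt)
            cur = nxt
        if len(walk) == n_edges + 1:
            return "".join(walk)
    logger.warning("dinucleotide shuffle failed after %d tries; "
                   "falling back to mononucleotide shuffle", max_tries)
    return mononucleotide_shuffle(seq, rng)


@dataclass
class FdrEstimate:
    """Empirical FDR from shuffled-promoter rescanning.

    ``fdr`` is None (undefined sentinel) when no observed hits exist.
    """

    fdr: float | None
    observed_hits: int
    mean_shuffled_hits: float
    n_shuffles: int
    z_threshold: float


def estimate_fdr(
    model: MotifModel,
    promoters: Mapping[str, str],
    z_threshold: float = Z_THRESHOLD,
    n_shuffles: int = 5,
    seed: int | np.random.Generator = 0,
    shuffle: str = "mono",
) -> FdrEstimate:
    """Empirical motif-hit FDR by rescanning shuffled promoters.

    Each promoter is composition-preservingly shuffled ``n_shuffles`` times
    (``shuffle`` = ``"mono"`` or ``"di"``) and rescanned; shuffled raw scores
    are standardized against the observed score distribution so hit counts
    are comparable.  FDR = mean shuffled hit count / observed hit count.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffler = {"mono": mononucleotide_shuffle, "di": dinucleotide_shuffle}[shuffle]

    obs = scan_promoters(promoters, model)
    vals = obs["raw_score"].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    mean, sd = float(vals[finite].mean()), float(np.std(vals[finite], ddof=0))
    if sd == 0:
        raise ValueError("observed scores have zero spread; FDR undefined")
    observed_hits = int(((vals - mean) / sd >= z_threshold).sum())

    null_counts = []
    for _ in range(n_shuffles):
        shuffled = {g: shuffler(s, rng) for g, s in promoters.items()}
        null = scan_promoters(shuffled, model)["raw_score"].to_numpy(dtype=float)
        null_counts.append(int(((null - mean) / sd >= z_threshold).sum()))
    mean_null = float(np.mean(null_counts))
    fdr = (mean_null / observed_hits) if observed_hits > 0 else None
    return FdrEstimate(
        fdr=fdr,
        observed_hits=observed_hits,
        mean_shuffled_hits=mean_null,
        n_shuffles=n_shuffles,
        z_threshold=z_threshold,
    )
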