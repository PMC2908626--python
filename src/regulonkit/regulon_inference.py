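"""Phylogenetic profiles, Jaccard similarity and regulon assignment.

Regulators that recognize near-identical DNA sites (e.g. FNR, FixK and DNR)
cannot be told apart by the motif alone.  The discriminating signal is
phylogenetic: a conserved target gene should co-occur, across species, with
the regulator that controls it.  Both the presence of a regulator sub-family
and the presence of a significant binding site within an ortholog group form
Boolean vectors over a fixed species list; each target group is assigned to
the regulator whose profile is most similar by the Jaccard coefficient
J(A,B) = |A n B| / |A u B|, provided the similarity reaches the cutoff
(default 20%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

#: default z bounds for the moderate/strong cells of the regulon matrix
MODERATE_Z = 2.0
STRONG_Z = 3.0


@dataclass
class PhyloProfile:
    """Boolean presence vector over a fixed, shared species order."""

    species: tuple[str, ...]
    present: np.ndarray

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.present = np.asarray(self.present, dtype=bool)
        if len(self.species) != len(self.present):
            raise ValueError("profile vector length must equal species count")

    def n_present(self) -> int:
        return int(self.present.sum())


def build_regulator_profile(
    member_genes: Iterable[str],
    gene_species: Mapping[str, str],
    species_order: Sequence[str],
) -> PhyloProfile:
    """Presence profile of a regulator sub-family: true where the species has
    at least one member (paralogs collapse to a single true entry)."""
    members = list(member_genes)
    if not members:
        raise ValueError("empty regulator sub-family")
    return _presence_profile(members, gene_species, species_order, lambda g: True)


def build_target_profile(
    member_genes: Iterable[str],
    significant: Mapping[str, bool],
    gene_species: Mapping[str, str],
    species_order: Sequence[str],
) -> PhyloProfile:
    """Motif-occurrence profile of an ortholog group.

    A species is true iff it contains at least one group member whose
    propagated promoter score is significant.  Species where the group is
    absent and species where no member is significant are both false; the
    distinction is retained only in the regulon matrix.
    """
    return _presence_profile(
        list(member_genes), gene_species, species_order,
        lambda g: bool(significant.get(g, False)),
    )


def _presence_profile(members, gene_species, species_order, predicate) -> PhyloProfile:
    index = {s: i for i, s in enumerate(species_order)}
    present = np.zeros(len(species_order), dtype=bool)
    for g in members:
        sp = gene_species.get(g)
        if sp is None:
            raise ValueError(f"gene {g!r} has no species mapping")
        if sp not in index:
            raise ValueError(f"species {sp!r} absent from the run's species list")
        if predicate(g):
            present[index[sp]] = True
    return PhyloProfile(species=tuple(species_order), present=present)


def jaccard(a: PhyloProfile, b: PhyloProfile) -> float:
    """Jaccard coefficient |A n B| / |A u B| of two profiles.

    Profiles must share the species order.  Two all-false profiles return 0:
    an empty profile carries no assignable signal.
    """
    if a.species != b.species:
        raise ValueError("profiles must share an identical species order")
    union = int(np.logical_or(a.present, b.present).sum())
    if union == 0:
        return 0.0
    inter = int(np.logical_and(a.present, b.present).sum())
    return inter / union


@dataclass
class RegulonAssignment:
    """Assignment of one ortholog group to its best-matching regulator."""

    group_id: str
    regulator: str  # regulator name or UNASSIGNED
    jaccard: float
    per_regulator: dict[str, float]
    tie: bool


def assign_targets(
    target_profiles: Mapping[str, PhyloProfile],
    regulator_profiles: Mapping[str, PhyloProfile],
    cutoff: float = 0.2,
) -> list[RegulonAssignment]:
    """Assign each target group to the regulator with the most similar profile.

    A group is assigned to the argmax-Jaccard regulator if the maximum
    reaches ``cutoff`` (default 20%), else UNASSIGNED.  Exact ties go to the
    first regulator in the declared ``regulator_profiles`` order with the tie
    flag set, so outputs are deterministic and ties auditable.
    """
    if not regulator_profiles:
        raise ValueError("at least one regulator profile is required")
    reg_names = list(regulator_profiles)
    out = []
    for gid, profile in target_profiles.items():
        js = {r: jaccard(profile, regulator_profiles[r]) for r in reg_names}
        best = max(js.values())
        winners = [r for r in reg_names if js[r] == best]
        if best >= cutoff:
            out.append(RegulonAssignment(
                group_id=gid, regulator=winners[0], jaccard=best,
                per_regulator=js, tie=len(winners) > 1,
            ))
        else:
            out.append(RegulonAssignment(
                group_id=gid, regulator=UNASSIGNED, jaccard=best,
                per_regulator=js, tie=False,
            ))
    return out


def assignments_frame(assignments: Iterable[RegulonAssignment]) -> pd.DataFrame:
    """Tabular view of assignments (one row per group)."""
    rows = []
    for a in assignments:
        row = {"group_id": a.group_id, "regulator": a.regulator,
               "jaccard": a.jaccard, "tie": a.tie}
        row.update({f"J_{r}": v for r, v in a.per_regulator.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# regulon matrix cell states, from no signal to strongest
NO_ORTHOLOG = "no_ortholog"
ORTHOLOG_NO_MOTIF = "ortholog_no_motif"
MODERATE_MOTIF = "moderate_motif"
STRONG_MOTIF = "strong_motif"

_STATE_ORDER = [NO_ORTHOLOG, ORTHOLOG_NO_MOTIF, MODERATE_MOTIF, STRONG_MOTIF]


def regulon_matrix(
    groups: Mapping[str, Sequence[str]],
    gene_z: Mapping[str, float],
    gene_species: Mapping[str, str],
    species_order: Sequence[str],
    moderate: float = MODERATE_Z,
    strong: float = STRONG_Z,
) -> pd.DataFrame:
    """Species x ortholog-group matrix of motif-evidence states.

    Cell state per (species, group): ``no_ortholog`` if the species lacks the
    group; otherwise graded by the best propagated z among the species'
    members — ``ortholog_no_motif`` below ``moderate``, ``moderate_motif`` in
    [moderate, strong), ``strong_motif`` at or above ``strong``.
    """
    for s in set(gene_species.values()):
        if s not in set(species_order):
            raise ValueError(f"species {s!r} not in the requested species order")
    mat = pd.DataFrame(NO_ORTHOLOG, index=list(species_order), columns=list(groups))
    for gid, members in groups.items():
        best: dict[str, float] = {}
        for g in members:
            sp = gene_species[g]
            z = gene_z.get(g, float("-inf"))
            if sp not in best or z > best[sp]:
                best[sp] = z
        for sp, z in best.items():
            if z >= strong:
                state = STRONG_MOTIF
            elif z >= moderate:
                state = MODERATE_MOTIF
            else:
                state = ORTHOLOG_NO_MOTIF
            mat.loc[sp, gid] = state
    return mat


_STATE_COLORS = {
    NO_ORTHOLOG: "#ffffff",
    ORTHOLOG_NO_MOTIF: "#000000",
    MODERATE_MOTIF: "#ff8c00",
    STRONG_MOTIF: "#ffd700",
}


def plot_regulon_matrix(matrix: pd.DataFrame, path: str | None = None):
    """Render the regulon matrix as a colored grid (white / black / orange /
    yellow for absent / ortholog only / moderate / strong motif evidence)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    codes = matrix.replace({s: i for i, s in enumerate(_STATE_ORDER)}).to_numpy(dtype=int)
    cmap = ListedColormap([_STATE_COLORS[s] for s in _STATE_ORDER])
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * matrix.shape[1]), max(3, 0.2 * matrix.shape[0]))
    )
    ax.imshow(codes, cmap=cmap, vmin=0, vmax=3, aspect="auto", interpolation="none")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=5)
    ax.set_xlabel("ortholog group")
    ax.set_ylabel("species")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=200)
        plt.close(fig)
        return None
    return fig


def cross_regulon_conservation(
    reference_groups: Sequence[str],
    groups: Mapping[str, Sequence[str]],
    significant: Mapping[str, bool],
    gene_species: Mapping[str, str],
    species_order: Sequence[str],
) -> pd.DataFrame:
    """Conservation of a reference regulon across species.

    For a declared reference set of ortholog groups (e.g. an experimentally
    determined regulon), counts per species how many reference groups have an
    ortholog present and how many of those carry a significant motif.
    Returns a DataFrame indexed by species with columns ``n_present`` and
    ``n_with_motif``.
    """
    unknown = [g for g in reference_groups if g not in groups]
    if unknown:
        raise ValueError(f"unknown reference group id(s): {unknown[:5]}")
    present = pd.DataFrame(False, index=list(species_order), columns=list(reference_groups))
    with_motif = present.copy()
    for gid in reference_groups:
        for g in groups[gid]:
            sp = gene_species[g]
            present.loc[sp, gid] = True
            if significant.get(g, False):
                with_motif.loc[sp, gid] = True
    return pd.DataFrame(
        {
            "n_present": present.sum(axis=1).astype(int),
            "n_with_motif": with_motif.sum(axis=1).astype(int),
        }
    )
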