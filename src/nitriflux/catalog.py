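"""MAG quality filtering, ANI dereplication and novelty flagging.

Metagenome-assembled genomes (MAGs) are graded by CheckM-style
completeness and contamination: "medium quality" is ≥50% complete with
≤10% contamination, "high quality" ≥90% / ≤5%. Redundant genomes
recovered from overlapping assemblies are collapsed at the species-level
boundary of 95% average nucleotide identity (ANI): genomes are linked
whenever a pair's ANI reaches the threshold, clusters are the connected
components of that graph (single linkage, matching dRep's secondary
clustering semantics), and one representative per cluster is chosen by a
quality score (completeness − 5 × contamination) with deterministic
tie-breaks. Genomic novelty relative to a reference set uses the same
currency: a query is novel when its best ANI to any reference falls
strictly below the threshold; an unrecorded pair means no detectable
similarity and counts as below threshold.

ANI computation itself (MASH/ANImf/fastANI) is upstream tooling; this
module consumes a precomputed pairwise ANI table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import InputError


@dataclass(frozen=True)
class GenomeRecord:
    """One genome/MAG with its quality metrics.

    ``completeness`` and ``contamination`` in percent, ``length_bp`` the
    assembly length; ``source`` distinguishes study MAGs from reference
    genomes used for novelty calls.
    """

    genome_id: str
    completeness: float
    contamination: float
    length_bp: int
    taxonomy: str = ""
    source: str = "study"

    def __post_init__(self):
        if not (0 <= self.completeness <= 100):
            raise InputError(f"{self.genome_id}: completeness outside [0, 100]")
        if self.contamination < 0:
            raise InputError(f"{self.genome_id}: contamination must be >= 0")
        if self.length_bp <= 0:
            raise InputError(f"{self.genome_id}: length_bp must be positive")


class ANIMatrix:
    """Pairwise ANI percentages with missing pairs allowed.

    Stored as a dense symmetric matrix over ``ids`` with NaN for
    unrecorded pairs; a missing pair is treated as "no detectable
    similarity" — below any threshold. The diagonal is 100 by identity.
    """

    def __init__(self, ids, matrix: np.ndarray):
        self.ids = list(ids)
        mat = np.array(matrix, dtype=float)
        if mat.shape != (len(self.ids), len(self.ids)):
            raise InputError("ANI matrix shape does not match id list")
        if mat.size:
            both = ~np.isnan(mat) & ~np.isnan(mat.T)
            if np.any(np.abs(np.where(both, mat - mat.T, 0.0)) > 1e-9):
                raise InputError("ANI matrix is not symmetric")
            # a pair recorded in one orientation only is symmetrized
            mat = np.where(np.isnan(mat) & ~np.isnan(mat.T), mat.T, mat)
            if (~np.isnan(mat) & ((mat < 0) | (mat > 100))).any():
                raise InputError("ANI values must lie in [0, 100]")
        np.fill_diagonal(mat, 100.0)
        self.matrix = mat
        self._pos = {g: i for i, g in enumerate(self.ids)}

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, ids=None) -> "ANIMatrix":
        """Build from a sparse long-format table.

        ``pairs`` has columns ``genome_id_1``, ``genome_id_2``,
        ``ani_percent``; pairs are symmetrized, absent pairs stay NaN.
        ``ids`` optionally fixes the id universe (genomes with no
        recorded pair at all).
        """
        required = {"genome_id_1", "genome_id_2", "ani_percent"}
        missing = required - set(pairs.columns)
        if missing:
            raise InputError(f"ANI table missing columns {sorted(missing)}")
        if ids is None:
            ids = sorted(set(pairs["genome_id_1"]) | set(pairs["genome_id_2"]))
        else:
            ids = list(ids)
            unknown = (set(pairs["genome_id_1"]) | set(pairs["genome_id_2"])) - set(ids)
            if unknown:
                raise InputError(f"ANI table references unknown genome(s): {sorted(unknown)}")
        pos = {g: i for i, g in enumerate(ids)}
        mat = np.full((len(ids), len(ids)), np.nan)
        for a, b, v in pairs[["genome_id_1", "genome_id_2", "ani_percent"]].itertuples(index=False):
            i, j = pos[a], pos[b]
            v = float(v)
            for x, y in ((i, j), (j, i)):
                if not np.isnan(mat[x, y]) and abs(mat[x, y] - v) > 1e-9:
                    raise InputError(f"conflicting ANI for pair ({a}, {b})")
                mat[x, y] = v
        return cls(ids, mat)

    def get(self, a: str, b: str) -> float:
        """ANI for one pair (NaN if unrecorded)."""
        return float(self.matrix[self._pos[a], self._pos[b]])

    def to_pairs(self) -> pd.DataFrame:
        """Long-format upper-triangle table of recorded pairs."""
        rows = []
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                v = self.matrix[i, j]
                if not np.isnan(v):
                    rows.append((a, self.ids[j], v))
        return pd.DataFrame(rows, columns=["genome_id_1", "genome_id_2", "ani_percent"])


@dataclass
class DereplicationResult:
    """Partition of genomes into ANI clusters with chosen representatives."""

    clusters: dict        # cluster_id -> sorted list of genome ids
    representatives: dict  # cluster_id -> genome id
    scores: dict          # genome id -> selection score

    def cluster_of(self) -> dict:
        """genome id -> cluster_id."""
        return {g: c for c, members in self.clusters.items() for g in members}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_quality(
    genomes, min_completeness: float = 50.0, max_contamination: float = 10.0
) -> list:
    """Keep genomes meeting completeness ≥ min AND contamination ≤ max.

    Comparisons are inclusive, so a genome exactly at (50, 10) passes the
    medium-quality filter. Input order is preserved.
    """
    if not (0 <= min_completeness <= 100) or max_contamination < 0:
        raise InputError("quality thresholds out of range")
    return [
        g
        for g in genomes
        if g.completeness >= min_completeness and g.contamination <= max_contamination
    ]


def drep_score(genome: GenomeRecord, contamination_weight: float = 5.0) -> float:
    """Representative-selection score: completeness − weight × contamination."""
    return genome.completeness - contamination_weight * genome.contamination


def dereplicate(
    ani: ANIMatrix,
    genomes,
    threshold: float = 95.0,
    contamination_weight: float = 5.0,
) -> DereplicationResult:
    """Cluster genomes at an ANI threshold and pick a representative each.

    Clusters are connected components of the graph with an edge wherever
    ANI ≥ threshold (single linkage: chains merge transitively). The
    representative maximizes completeness − 5 × contamination; ties break
    to the longer genome, then to the lexicographically smaller id.
    Cluster ids are assigned in order of each cluster's smallest genome id.
    """
    genomes = list(genomes)
    by_id = {g.genome_id: g for g in genomes}
    if len(by_id) != len(genomes):
        raise InputError("duplicate genome ids")
    if set(by_id) - set(ani.ids):
        raise InputError(
            f"ANI matrix missing genome(s): {sorted(set(by_id) - set(ani.ids))}"
        )
    ids = [g.genome_id for g in genomes]
    idx = [ani.ids.index(g) for g in ids]
    sub = ani.matrix[np.ix_(idx, idx)]
    with np.errstate(invalid="ignore"):
        adj = np.nan_to_num(sub, nan=-np.inf) >= threshold
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    members: dict = {}
    for gid, lab in zip(ids, labels):
        members.setdefault(lab, []).append(gid)
    ordered = sorted(members.values(), key=lambda ms: min(ms))
    clusters, representatives = {}, {}
    scores = {gid: drep_score(by_id[gid], contamination_weight) for gid in ids}
    for k, ms in enumerate(ordered):
        cid = f"cluster_{k}"
        clusters[cid] = sorted(ms)
        best = max((scores[g], by_id[g].length_bp) for g in ms)
        representatives[cid] = min(
            g for g in ms if (scores[g], by_id[g].length_bp) == best
        )
    return DereplicationResult(clusters, representatives, scores)


def flag_novel(
    query, references, ani: ANIMatrix, threshold: float = 95.0
) -> pd.Series:
    """Flag query genomes with no reference at or above the ANI threshold.

    Novel ⇔ max ANI to any reference < threshold (strict: exactly 95.0
    matches a known species). Query-reference pairs absent from the ANI
    table count as dissimilar; a query with no recorded pairs is novel.
    """
    ref_ids = [r.genome_id for r in references]
    flags = {}
    for q in query:
        best = -np.inf
        for r in ref_ids:
            if q.genome_id in ani._pos and r in ani._pos:
                v = ani.get(q.genome_id, r)
                if not np.isnan(v):
                    best = max(best, v)
        flags[q.genome_id] = bool(best < threshold)
    return pd.Series(flags, name="novel", dtype=bool)


def select_longest_representative(clusters: dict, lengths: dict) -> dict:
    """Pick the longest sequence per cluster (ties → lexicographically first).

    The rule used when collapsing a redundant sequence catalog: the
    longest member represents the cluster. ``clusters`` maps cluster id →
    member ids; ``lengths`` maps member id → length in bp.
    """
    out = {}
    for cid, members in clusters.items():
        missing = [m for m in members if m not in lengths]
        if missing:
            raise InputError(f"missing length for sequence(s): {missing}")
        longest = max(lengths[m] for m in members)
        out[cid] = min(m for m in members if lengths[m] == longest)
    return out
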