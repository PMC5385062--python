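"""Screening and clustering of unidentifiable ITS OTUs.

Identity definition
-------------------
Pairwise identity is computed from a global alignment with free end gaps
(match +1, mismatch -1, gap open -2.5, gap extend -2).  Identity is
``matches / aligned columns`` over the end-gap-free span of that alignment,
and the reported ``overlap`` ("coverage") is the column count of the same
span.  A pair is linkable in single-linkage clustering only when
``identity >= threshold`` *and* ``overlap >= min_overlap`` (default 100
bases); the coverage requirement also guards the reference screen against
short spurious high-identity spans between unrelated sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd
from Bio import Align

from .io_formats import OtuRecord, ReferenceRecord, ValidationError

__all__ = [
    "IdentityResult",
    "OtuCluster",
    "TargetSet",
    "pairwise_identity",
    "IdentityCache",
    "screen_unidentifiable",
    "single_linkage_cluster",
    "select_targets",
]


@dataclass(frozen=True)
class IdentityResult:
    """Identity over, and length of, the end-gap-free aligned span."""

    identity: float
    overlap: int


@dataclass
class OtuCluster:
    cluster_id: str
    member_otu_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_otu_ids)


@dataclass
class TargetSet:
    """Primer-design targets: single OTUs plus groups of near-identical OTUs."""

    individual_targets: list[str] = field(default_factory=list)
    grouped_targets: list[tuple[str, list[str]]] = field(default_factory=list)

    def all_target_otus(self) -> list[str]:
        otus = list(self.individual_targets)
        for _, members in self.grouped_targets:
            otus.extend(members)
        return otus


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -2.0
    # free end gaps on both sequences
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> IdentityResult:
    """Identity and overlap of the best free-end-gap global alignment.

    Symmetric in its arguments (inputs are ordered canonically before
    alignment so tie-breaking cannot depend on argument order).
    """
    if not seq_a or not seq_b:
        raise ValidationError("pairwise_identity: empty sequence")
    a, b = sorted((seq_a.upper(), seq_b.upper()))
    alignment = _ALIGNER.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    first = max(_first_residue(row_a), _first_residue(row_b))
    last = min(_last_residue(row_a), _last_residue(row_b))
    if last < first:
        return IdentityResult(identity=0.0, overlap=0)
    columns = last - first + 1
    matches = sum(
        1
        for i in range(first, last + 1)
        if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    return IdentityResult(identity=matches / columns, overlap=columns)


def _first_residue(row: str) -> int:
    return len(row) - len(row.lstrip("-"))


def _last_residue(row: str) -> int:
    return len(row.rstrip("-")) - 1


class IdentityCache:
    """Memoizes pairwise identities keyed by unordered sequence-id pairs."""

    def __init__(
        self,
        sequences: dict[str, str],
        identity_fn: Callable[[str, str], IdentityResult] = pairwise_identity,
    ) -> None:
        self.sequences = sequences
        self._identity_fn = identity_fn
        self._cache: dict[frozenset[str], IdentityResult] = {}

    def __call__(self, id_a: str, id_b: str) -> IdentityResult:
        key = frozenset((id_a, id_b))
        if key not in self._cache:
            self._cache[key] = self._identity_fn(
                self.sequences[id_a], self.sequences[id_b]
            )
        return self._cache[key]


def screen_unidentifiable(
    otus: Sequence[OtuRecord],
    references: Sequence[ReferenceRecord],
    threshold: float = 0.80,
    min_overlap: int = 100,
) -> tuple[list[OtuRecord], pd.DataFrame]:
    """OTUs whose best reference identity falls below ``threshold``.

    A reference hit only counts when its aligned span is at least
    ``min_overlap`` bases.  Returns the retained OTUs and a per-OTU report
    (best reference, identity, overlap, retained flag).
    """
    if not references:
        raise ValidationError(
            "screen_unidentifiable: empty reference set (cannot certify "
            "unidentifiability without references)"
        )
    retained: list[OtuRecord] = []
    rows = []
    for otu in otus:
        best_identity, best_overlap, best_ref = 0.0, 0, ""
        for ref in references:
            result = pairwise_identity(otu.sequence, ref.sequence)
            if result.overlap < min_overlap:
                continue
            if result.identity > best_identity:
                best_identity, best_overlap = result.identity, result.overlap
                best_ref = ref.ref_id
        keep = best_identity < threshold
        if keep:
            retained.append(otu)
        rows.append(
            {
                "otu_id": otu.otu_id,
                "best_reference": best_ref,
                "best_identity": best_identity,
                "best_overlap": best_overlap,
                "retained": keep,
            }
        )
    return retained, pd.DataFrame(rows)


class _UnionFind:
    def __init__(self, items: Sequence[str]) -> None:
        self.parent = {item: item for item in items}

    def find(self, item: str) -> str:
        while self.parent[item] != item:
            self.parent[item] = self.parent[self.parent[item]]
            item = self.parent[item]
        return item

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def components(self) -> list[list[str]]:
        groups: dict[str, list[str]] = {}
        for item in self.parent:
            groups.setdefault(self.find(item), []).append(item)
        return [sorted(members) for members in groups.values()]


def single_linkage_cluster(
    otus: Sequence[OtuRecord],
    threshold: float = 0.80,
    min_overlap: int = 100,
    identity: IdentityCache | None = None,
) -> list[OtuCluster]:
    """Single-linkage clusters of OTUs at an identity/coverage threshold.

    Two OTUs are linked iff ``identity >= threshold`` and
    ``overlap >= min_overlap``; clusters are the connected components of the
    link graph.  Output is canonical (clusters sorted by their smallest
    member id, members sorted), hence independent of input order.
    """
    if not otus:
        raise ValidationError("single_linkage_cluster: need at least one OTU")
    ids = sorted(o.otu_id for o in otus)
    if identity is None:
        identity = IdentityCache({o.otu_id: o.sequence for o in otus})
    uf = _UnionFind(ids)
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1 :]:
            result = identity(id_a, id_b)
            if result.identity >= threshold and result.overlap >= min_overlap:
                uf.union(id_a, id_b)
    components = sorted(uf.components(), key=lambda members: members[0])
    return [
        OtuCluster(cluster_id=f"C{idx:03d}", member_otu_ids=members)
        for idx, members in enumerate(components, start=1)
    ]


def select_targets(
    clusters: Sequence[OtuCluster],
    otus: Sequence[OtuRecord],
    group_identity: float = 0.95,
    major_cluster_size: int = 10,
    min_overlap: int = 100,
    per_cluster_cap: int | None = None,
    identity: IdentityCache | None = None,
) -> TargetSet:
    """Choose primer-design targets from clusters.

    Within each cluster, connected components at identity strictly above
    ``group_identity`` become grouped targets when all pairwise identities
    clear the bar (otherwise the component is split into individual
    targets); singleton components are individual targets.  Every cluster
    contributes at least one target, so every major cluster
    (size > ``major_cluster_size``) is covered.  With ``per_cluster_cap``
    set, targets in a cluster are ranked by summed member read counts
    (ties: lexicographic id) and only the top targets are kept.
    """
    by_id = {o.otu_id: o for o in otus}
    if identity is None:
        identity = IdentityCache({o.otu_id: o.sequence for o in otus})
    target_set = TargetSet()
    for cluster in clusters:
        members = sorted(cluster.member_otu_ids)
        uf = _UnionFind(members)
        for i, id_a in enumerate(members):
            for id_b in members[i + 1 :]:
                result = identity(id_a, id_b)
                if result.identity > group_identity and result.overlap >= min_overlap:
                    uf.union(id_a, id_b)
        grouped: list[list[str]] = []
        individual: list[str] = []
        for component in uf.components():
            if len(component) >= 2 and _all_pairs_above(
                component, identity, group_identity, min_overlap
            ):
                grouped.append(component)
            else:
                individual.extend(component)
        candidates: list[tuple[float, str, list[str] | None]] = []
        for component in grouped:
            weight = sum(by_id[m].total_count for m in component)
            candidates.append((-weight, component[0], component))
        for otu_id in individual:
            candidates.append((-by_id[otu_id].total_count, otu_id, None))
        candidates.sort()
        if per_cluster_cap is not None:
            candidates = candidates[:per_cluster_cap]
        group_index = 0
        for _, anchor, component in candidates:
            if component is None:
                target_set.individual_targets.append(anchor)
            else:
                group_index += 1
                target_set.grouped_targets.append(
                    (f"{cluster.cluster_id}_g{group_index}", component)
                )
    return target_set


def _all_pairs_above(
    members: Sequence[str],
    identity: IdentityCache,
    group_identity: float,
    min_overlap: int,
) -> bool:
    for i, id_a in enumerate(members):
        for id_b in members[i + 1 :]:
            result = identity(id_a, id_b)
            if result.identity <= group_identity or result.overlap < min_overlap:
                return False
    return True
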