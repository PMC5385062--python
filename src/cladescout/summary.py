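"""Bookkeeping summaries of a targeting campaign and its recovered groups.

These are the small arithmetic identities a study report is built from:
how many OTUs were targeted (individually plus inside grouped targets),
what fraction yielded sequence, how the recovered clades and singleton
branches tally up, and which share of groups a focal phylum or the
multi-OTU subset represents.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ValidationError

__all__ = ["TargetingSummary", "GroupSummary"]


@dataclass(frozen=True)
class TargetingSummary:
    """Counts of a primer-targeting campaign.

    ``n_individual`` single-OTU targets, ``n_groups`` grouped targets
    jointly containing ``n_grouped_otus`` OTUs, and ``n_failed`` OTUs for
    which sequencing failed completely.
    """

    n_individual: int
    n_groups: int
    n_grouped_otus: int
    n_failed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individual, self.n_groups, self.n_grouped_otus, self.n_failed) < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_grouped_otus < self.n_groups:
            raise ValidationError("each grouped target needs at least one OTU")
        if self.n_failed > self.n_individual + self.n_grouped_otus:
            raise ValidationError("more failures than targeted OTUs")

    @property
    def n_targeted_otus(self) -> int:
        return self.n_individual + self.n_grouped_otus

    @property
    def n_recovered(self) -> int:
        return self.n_targeted_otus - self.n_failed

    @property
    def recovery_rate_pct(self) -> float:
        if self.n_targeted_otus == 0:
            raise ValidationError("no targeted OTUs")
        return 100.0 * self.n_recovered / self.n_targeted_otus


@dataclass(frozen=True)
class GroupSummary:
    """Counts of recovered higher-rank groups (clades + singleton branches)."""

    n_clades: int
    n_branches: int
    n_focal_clades: int = 0
    n_focal_branches: int = 0
    n_multi_otu_groups: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clades, self.n_branches) < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_focal_clades > self.n_clades or self.n_focal_branches > self.n_branches:
            raise ValidationError("focal groups exceed totals")
        if self.n_multi_otu_groups > self.n_groups:
            raise ValidationError("multi-OTU groups exceed totals")

    @property
    def n_groups(self) -> int:
        return self.n_clades + self.n_branches

    @property
    def focal_share_pct(self) -> float:
        if self.n_groups == 0:
            raise ValidationError("no groups")
        return 100.0 * (self.n_focal_clades + self.n_focal_branches) / self.n_groups

    @property
    def multi_otu_share_pct(self) -> float:
        if self.n_groups == 0:
            raise ValidationError("no groups")
        return 100.0 * self.n_multi_otu_groups / self.n_groups
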