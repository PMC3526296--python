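"""End-to-end convenience: detect losses, infer branches, run the null models.

Ties the modules together for the common case of a complete input bundle
(real files read via pandas, or a :class:`~cneloss.simulate.SyntheticDataset`).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import nulls
from .detection import StatusMatrix, build_status_matrix
from .phylo import Phylogeny
from .simulate import SyntheticDataset

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    matrix: StatusMatrix
    stats: nulls.BranchLossStats
    events: list[tuple[str, str]]
    e2: float
    e3: float
    e2_per_combo: dict
    e3_per_combo: dict
    null: nulls.NullResult | None

    def summary(self, k: int) -> nulls.NullSummary:
        if self.null is None:
            raise ValueError("simulation was not run")
        return self.null.summary(k)


def run_pipeline(
    dataset: SyntheticDataset,
    iterations: int = 1000,
    seed: int | None = None,
    placement: str = "ancestral",
    simulate: bool = True,
    track_combos: bool = True,
) -> PipelineResult:
    """Classify every CNE x species cell, infer loss branches, and compare
    observed independent-loss counts to the uniform null (exact expectation
    and, optionally, the constrained reassignment simulation)."""
    tree: Phylogeny = dataset.tree
    matrix = build_status_matrix(
        dataset.cnes, dataset.evidence, dataset.gaps, dataset.hits, tree
    )
    stats = nulls.eligibility_counts(matrix, tree, placement)
    events = nulls.build_loss_event_list(stats.events_per_cne, tree)
    e2, e2_combo = nulls.expected_independent(stats, 2)
    e3, e3_combo = nulls.expected_independent(stats, 3)
    null = None
    if simulate:
        null = nulls.simulate_null(
            events,
            matrix,
            tree,
            iterations=iterations,
            rng=seed,
            placement=placement,
            track_combos=track_combos,
        )
    return PipelineResult(
        matrix=matrix,
        stats=stats,
        events=events,
        e2=e2,
        e3=e3,
        e2_per_combo=e2_combo,
        e3_per_combo=e3_combo,
        null=null,
    )
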