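"""qRT-PCR transcript normalization.

Absolute transcript counts are normalized to the housekeeping gene PPIB
(peptidylprolyl isomerase B) and expressed as transcripts per 1000 PPIB
transcripts; for bar-chart style comparisons, each experiment's values
are additionally rescaled so that a chosen reference condition equals 1,
then averaged across independent experiments (mean +/- SEM, with the
experiment as the replication unit).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["normalize_to_ppib", "relative_to_reference", "aggregate_experiments"]


def normalize_to_ppib(target, ppib):
    """Transcripts per 1000 PPIB transcripts: ``1000 * target / ppib``."""
    target = np.asarray(target, dtype=float)
    ppib = np.asarray(ppib, dtype=float)
    if np.any(ppib <= 0):
        raise ValueError("PPIB transcript count must be > 0 for normalization")
    return 1000.0 * target / ppib


def relative_to_reference(
    values: pd.Series, reference_condition: str
) -> pd.Series:
    """Scale a condition -> value Series so the reference maps to 1."""
    if reference_condition not in values.index:
        raise ValueError(f"reference condition {reference_condition!r} missing")
    ref = float(values[reference_condition])
    if ref <= 0:
        raise ValueError("reference condition value must be > 0")
    return values / ref


def aggregate_experiments(
    table: pd.DataFrame, reference_condition: str
) -> pd.DataFrame:
    """Per-experiment PPIB normalization and reference scaling, then
    mean +/- SEM across experiments.

    ``table`` columns: experiment, condition, gene, target_transcripts,
    ppib_transcripts.  Returns one row per (gene, condition) with the
    mean relative value, SEM (sd/sqrt(n), ddof=1) and n, plus the mean
    absolute per-1000-PPIB level.
    """
    required = {"experiment", "condition", "gene", "target_transcripts",
                "ppib_transcripts"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    work = table.copy()
    work["per_1000_ppib"] = normalize_to_ppib(
        work["target_transcripts"], work["ppib_transcripts"]
    )
    rel_frames = []
    for (exp, gene), grp in work.groupby(["experiment", "gene"]):
        series = grp.set_index("condition")["per_1000_ppib"]
        rel = relative_to_reference(series, reference_condition)
        rel_frames.append(
            pd.DataFrame(
                {"experiment": exp, "gene": gene, "condition": rel.index,
                 "relative": rel.to_numpy(),
                 "per_1000_ppib": series.to_numpy()}
            )
        )
    rel_all = pd.concat(rel_frames, ignore_index=True)
    def _sem(x):
        x = np.asarray(x, dtype=float)
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    out = (
        rel_all.groupby(["gene", "condition"])
        .agg(
            mean_relative=("relative", "mean"),
            sem_relative=("relative", _sem),
            mean_per_1000_ppib=("per_1000_ppib", "mean"),
            n_experiments=("relative", "size"),
        )
        .reset_index()
    )
    return out
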