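"""Synthetic data for the epithelial-loss (LEL) organ-culture design.

The generator emulates a paired two-condition microarray experiment:
``n_subjects`` matched replicates, each contributing one reference sample
(intact mucosa, 0 h) and one treated sample (epithelium-depleted mucosa,
5 h).  Probe intensities are produced on the raw scanner scale through a
per-array affine calibration of an exponentiated log2 signal,

    y_ig = a_i + b_i * 2**(mu_g + subject_gs + delta_g*[treated]
                           + eps_mult) + eps_add,   clipped at 0,

where ``delta_g`` is the true log2 fold change (non-zero only for the
differential fraction), ``eps_mult`` is multiplicative (log2-scale) noise
and ``eps_add`` is additive scanner noise.  The affine pair (a_i, b_i) is
what variance-stabilizing normalization must recover.

A toy rooted ontology DAG with gene annotations, and an external
"reference study" differential gene list with controllable concordance,
complete the fixtures needed to exercise enrichment and overlap testing
with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "ExpressionDataset",
    "generate_expression_dataset",
    "generate_ontology",
    "generate_reference_study",
]


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class ExpressionDataset:
    """Probe x sample intensity matrix with its sample sheet.

    ``intensities``: DataFrame indexed by probe_id, columns = sample ids.
    ``sample_sheet``: one row per sample with ``sample_id``, ``subject_id``
    and ``condition`` in {"reference", "treated"}.
    ``probe_annotation``: Series probe_id -> gene symbol.
    """

    intensities: pd.DataFrame
    sample_sheet: pd.DataFrame
    probe_annotation: pd.Series

    def __post_init__(self) -> None:
        if list(self.sample_sheet["sample_id"]) != list(self.intensities.columns):
            raise ValueError("sample sheet rows must match matrix columns in order")
        if self.intensities.index.duplicated().any():
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup}")
        bad = set(self.sample_sheet["condition"]) - {"reference", "treated"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def check_paired(self) -> None:
        """Every subject must contribute exactly one sample per condition."""
        counts = self.sample_sheet.groupby(["subject_id", "condition"]).size()
        for subject in self.sample_sheet["subject_id"].unique():
            for cond in ("reference", "treated"):
                if counts.get((subject, cond), 0) != 1:
                    raise ValueError(
                        f"subject {subject!r} lacks exactly one {cond} sample"
                    )


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``probes`` holds one row per probe: probe_id, gene, is_de,
    true_log2fc (0 for null probes), annotated_terms (semicolon-joined,
    empty until an ontology is attached).  ``calibration`` holds the true
    per-array affine parameters (sample_id, offset, scale).
    """

    probes: pd.DataFrame
    calibration: pd.DataFrame

    @property
    def de_genes(self) -> set[str]:
        return set(self.probes.loc[self.probes["is_de"], "gene"])

    @property
    def up_genes(self) -> set[str]:
        sel = self.probes["true_log2fc"] > 0
        return set(self.probes.loc[sel, "gene"])

    @property
    def down_genes(self) -> set[str]:
        sel = self.probes["true_log2fc"] < 0
        return set(self.probes.loc[sel, "gene"])


@dataclass
class SimulationConfig:
    """Study conditions for the paired-design generator.

    Defaults mirror the organ-culture design: four matched subject pairs,
    a modest fraction of truly differential probes with log2 effects drawn
    from +/- N(2.5, 1) truncated at |lfc| >= 0.5 (top effects reach ~5),
    per-array affine calibration, and both multiplicative (log2-scale) and
    additive (intensity-scale) noise.
    """

    n_probes: int = 2000
    n_subjects: int = 4
    frac_de: float = 0.05
    lfc_mean: float = 2.5
    lfc_sd: float = 1.0
    lfc_min: float = 0.5
    frac_up: float = 0.5
    baseline_mean: float = 9.0
    baseline_sd: float = 1.5
    sigma_bio: float = 0.3
    sigma_add: float = 30.0
    sigma_mult: float = 0.1
    offsets: Sequence[float] | None = None
    scales: Sequence[float] | None = None
    offset_range: tuple[float, float] = (50.0, 200.0)
    scale_range: tuple[float, float] = (0.7, 1.4)
    noise_before_gain: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes <= 0 or self.n_subjects <= 0:
            raise InvalidConfigError("n_probes and n_subjects must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise InvalidConfigError("frac_de must lie in [0, 1]")
        if not 0.0 <= self.frac_up <= 1.0:
            raise InvalidConfigError("frac_up must lie in [0, 1]")
        for name in ("lfc_sd", "sigma_bio", "sigma_add", "sigma_mult"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        n_arrays = 2 * self.n_subjects
        for name, vals in (("offsets", self.offsets), ("scales", self.scales)):
            if vals is not None and len(vals) != n_arrays:
                raise InvalidConfigError(
                    f"{name} must have one entry per array ({n_arrays})"
                )
        if self.scales is not None and any(b <= 0 for b in self.scales):
            raise InvalidConfigError("all array scales must be > 0")
        if self.scale_range[0] <= 0:
            raise InvalidConfigError("scale_range must be positive")


def _gene_symbols(n: int, start: int = 1) -> list[str]:
    return [f"G{i:06d}" for i in range(start, start + n)]


def generate_expression_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, TruthTable]:
    """Simulate a paired two-condition probe intensity matrix.

    Returns the raw-scale dataset together with a :class:`TruthTable`
    recording every differential probe, its true log2 effect and the true
    per-array calibration.  Identical config (including seed) gives
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, S = config.n_probes, config.n_subjects
    n_arrays = 2 * S

    probe_ids = [f"P{i:06d}" for i in range(1, G + 1)]
    genes = _gene_symbols(G)

    n_de = int(round(config.frac_de * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    lfc = np.zeros(G)
    if n_de:
        mags = np.empty(n_de)
        remaining = np.arange(n_de)
        while remaining.size:
            draw = rng.normal(config.lfc_mean, config.lfc_sd, size=remaining.size)
            ok = np.abs(draw) >= config.lfc_min
            mags[remaining[ok]] = np.abs(draw[ok])
            remaining = remaining[~ok]
        signs = np.where(rng.random(n_de) < config.frac_up, 1.0, -1.0)
        lfc[de_idx] = signs * mags

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=G)

    if config.offsets is not None:
        a = np.asarray(config.offsets, dtype=float)
    else:
        a = rng.uniform(*config.offset_range, size=n_arrays)
    if config.scales is not None:
        b = np.asarray(config.scales, dtype=float)
    else:
        b = rng.uniform(*config.scale_range, size=n_arrays)

    subj_eff = rng.normal(0.0, config.sigma_bio, size=(G, S)) if config.sigma_bio else np.zeros((G, S))

    sample_ids, subject_ids, conditions = [], [], []
    for s in range(1, S + 1):
        sample_ids += [f"R{s}_0h", f"R{s}_5h"]
        subject_ids += [f"R{s}", f"R{s}"]
        conditions += ["reference", "treated"]

    log2_signal = np.empty((G, n_arrays))
    for j, (subj, cond) in enumerate(zip(subject_ids, conditions)):
        s = int(subj[1:]) - 1
        log2_signal[:, j] = mu + subj_eff[:, s] + (lfc if cond == "treated" else 0.0)
    if config.sigma_mult:
        log2_signal = log2_signal + rng.normal(0.0, config.sigma_mult, size=(G, n_arrays))

    signal = np.exp2(log2_signal)
    if config.sigma_add:
        noise = rng.normal(0.0, config.sigma_add, size=(G, n_arrays))
        if config.noise_before_gain:
            # amplifier noise: enters before the array gain, so its
            # post-gain sd scales with b_i and the glog model is exact
            raw = a[None, :] + b[None, :] * (signal + noise)
        else:
            raw = a[None, :] + b[None, :] * signal + noise
    else:
        raw = a[None, :] + b[None, :] * signal
    raw = np.clip(raw, 0.0, None)

    dataset = ExpressionDataset(
        intensities=pd.DataFrame(raw, index=pd.Index(probe_ids, name="probe_id"),
                                 columns=sample_ids),
        sample_sheet=pd.DataFrame(
            {"sample_id": sample_ids, "subject_id": subject_ids,
             "condition": conditions}
        ),
        probe_annotation=pd.Series(genes, index=probe_ids, name="gene"),
    )
    truth = TruthTable(
        probes=pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene": genes,
                "is_de": lfc != 0.0,
                "true_log2fc": lfc,
                "annotated_terms": ["" for _ in range(G)],
            }
        ),
        calibration=pd.DataFrame(
            {"sample_id": sample_ids, "offset": a, "scale": b}
        ),
    )
    return dataset, truth


def generate_ontology(
    n_terms: int, max_children: int, n_genes: int, seed: int = 0
) -> tuple["nx.DiGraph", dict[str, set[str]]]:
    """Build a toy rooted is-a DAG and direct gene->term annotations.

    Edges run child -> parent.  Term ``T0001`` is the single root; each
    later term attaches to one or two earlier terms (at most
    ``max_children`` children per parent), so the graph is acyclic by
    construction.  Each gene is directly annotated to one or more terms,
    biased toward the leaves so that ancestor propagation is non-trivial.
    """
    if n_terms < 1:
        raise InvalidConfigError("n_terms must be >= 1")
    if n_genes < 0:
        raise InvalidConfigError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:04d}" for i in range(1, n_terms + 1)]
    dag = nx.DiGraph()
    for t in terms:
        dag.add_node(t, name=f"toy process {t}")
    child_count = {t: 0 for t in terms}
    for i, term in enumerate(terms[1:], start=1):
        candidates = [t for t in terms[:i] if child_count[t] < max_children]
        if not candidates:
            candidates = terms[:i]
        n_parents = 1 if i < 3 or rng.random() < 0.7 else 2
        parents = rng.choice(len(candidates), size=min(n_parents, len(candidates)),
                             replace=False)
        for p in parents:
            parent = candidates[int(p)]
            dag.add_edge(term, parent)
            child_count[parent] += 1

    genes = _gene_symbols(n_genes)
    annotations: dict[str, set[str]] = {}
    # leaves (no incoming child edge) get most of the direct annotations
    leaves = [t for t in terms if dag.in_degree(t) == 0] or terms
    for g in genes:
        n_ann = 1 + int(rng.random() < 0.3)
        pool = leaves if rng.random() < 0.8 else terms
        chosen = rng.choice(len(pool), size=min(n_ann, len(pool)), replace=False)
        annotations[g] = {pool[int(c)] for c in chosen}
    return dag, annotations


def generate_reference_study(
    truth: TruthTable,
    universe_size: int,
    concordance: float,
    seed: int = 0,
    list_size: int | None = None,
    direction: str | None = None,
) -> tuple[set[str], set[str]]:
    """Simulate an external study's DE gene list and probe universe.

    The reference list shares ``ceil(concordance * |truth DE|)`` genes with
    the simulated truth (optionally restricted to one ``direction``, "up"
    or "down"); the remainder is drawn from the non-differential part of
    the universe.  Returns ``(reference_de_list, reference_universe)``.
    """
    if not 0.0 <= concordance <= 1.0:
        raise InvalidConfigError("concordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if direction == "up":
        de_genes = sorted(truth.up_genes)
    elif direction == "down":
        de_genes = sorted(truth.down_genes)
    elif direction is None:
        de_genes = sorted(truth.de_genes)
    else:
        raise InvalidConfigError("direction must be 'up', 'down' or None")

    all_genes = list(truth.probes["gene"])
    if universe_size < len(all_genes):
        raise InvalidConfigError("universe must cover all simulated genes")
    extra = _gene_symbols(universe_size - len(all_genes), start=len(all_genes) + 1)
    universe = set(all_genes) | set(extra)

    if list_size is None:
        list_size = len(de_genes)
    n_shared = min(int(np.ceil(concordance * len(de_genes))), list_size, len(de_genes))
    shared = rng.choice(len(de_genes), size=n_shared, replace=False)
    reference = {de_genes[int(i)] for i in shared}
    non_de = sorted(universe - set(sorted(truth.de_genes)))
    n_fill = list_size - len(reference)
    fill = rng.choice(len(non_de), size=n_fill, replace=False)
    reference |= {non_de[int(i)] for i in fill}
    return reference, universe
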