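"""Permutation test for the overlap of two differential gene lists.

To ask whether an in-vitro DE list shares more genes with a published
in-vivo DE list than chance would give, random gene lists of the model
list's size are drawn (without replacement) from the reference study's
probe universe; the distribution of their intersections with the
reference DE list forms the null.  The empirical p-value uses the
add-one convention (#{null >= observed} + 1)/(n_perm + 1), so a result
never exceeded by any of n_perm permutations reports p = 1/(n_perm+1),
printed as "<1/n_perm".  Because the draw is simple random sampling, the
null intersection is exactly hypergeometric, which provides a
deterministic cross-check (``p_exact``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "OverlapTestResult",
    "normalize_symbols",
    "observed_overlap",
    "hypergeometric_overlap_p",
    "permutation_overlap_test",
]


def normalize_symbols(genes) -> set[str]:
    """Upper-case and strip whitespace; drop empties."""
    out = set()
    for g in genes:
        g = str(g).strip().upper()
        if g:
            out.add(g)
    return out


@dataclass
class OverlapTestResult:
    observed: int
    n_perm: int
    null_sizes: np.ndarray
    p_empirical: float
    p_exact: float
    seed: int

    @property
    def p_report(self) -> str:
        """Printed form: "<1/n_perm" when no permutation reached the observed."""
        if int(np.sum(self.null_sizes >= self.observed)) == 0:
            return f"<{1.0 / self.n_perm:g}"
        return f"{self.p_empirical:g}"

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "n_perm": self.n_perm,
            "p_empirical": self.p_empirical,
            "p_report": self.p_report,
            "p_exact": self.p_exact,
            "null_mean": float(np.mean(self.null_sizes)),
            "null_max": int(np.max(self.null_sizes)),
            "seed": self.seed,
        }


def observed_overlap(model_list, reference_list) -> int:
    """Size of the intersection after symbol normalization."""
    return len(normalize_symbols(model_list) & normalize_symbols(reference_list))


def hypergeometric_overlap_p(
    observed: int, model_list_size: int, reference_de_size: int, universe_size: int
) -> float:
    """Exact upper tail P(X >= observed) for a random draw of the model
    list's size from the universe, counting hits in the reference list."""
    if not (
        0 <= observed <= min(model_list_size, reference_de_size)
        and model_list_size <= universe_size
        and reference_de_size <= universe_size
    ):
        raise ValueError(
            "inconsistent counts: observed={}, draw={}, reference={}, N={}".format(
                observed, model_list_size, reference_de_size, universe_size
            )
        )
    if observed == 0:
        return 1.0
    return float(hypergeom.sf(observed - 1, universe_size, reference_de_size,
                              model_list_size))


def permutation_overlap_test(
    model_list_size: int,
    reference_universe,
    reference_de_list,
    observed: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> OverlapTestResult:
    """Permutation null for a DE-list intersection.

    Draws ``n_perm`` random lists of ``model_list_size`` genes from the
    reference universe without replacement and records each one's
    intersection with the reference DE list.  Ties count as extreme and
    the add-one convention keeps p in (0, 1].
    """
    universe = sorted(normalize_symbols(reference_universe))
    ref = normalize_symbols(reference_de_list)
    if not ref <= set(universe):
        missing = sorted(ref - set(universe))[:5]
        raise ValueError(f"reference DE list not in universe (e.g. {missing})")
    if model_list_size > len(universe):
        raise ValueError("model_list_size exceeds the reference universe")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    is_ref = np.fromiter((g in ref for g in universe), dtype=bool,
                         count=len(universe))
    null_sizes = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        idx = rng.choice(len(universe), size=model_list_size, replace=False)
        null_sizes[i] = int(is_ref[idx].sum())
    p_emp = (int(np.sum(null_sizes >= observed)) + 1) / (n_perm + 1)
    p_exact = hypergeometric_overlap_p(
        observed, model_list_size, len(ref), len(universe)
    )
    return OverlapTestResult(
        observed=observed,
        n_perm=n_perm,
        null_sizes=null_sizes,
        p_empirical=p_emp,
        p_exact=p_exact,
        seed=seed,
    )
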