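"""Alpha-diversity indices for OTU abundance vectors.

Standard textbook estimators, implemented directly so that clone-library
and amplicon tables can be summarized without an external pipeline:
bias-corrected Chao1, ACE (rare-class threshold 10), Shannon (natural log
by default, base switchable), Simpson (1 - sum p_i^2), and Good's
coverage.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = ["chao1", "ace", "shannon", "simpson", "goods_coverage", "alpha_summary"]


def _validate(counts: Sequence[int]) -> list[int]:
    counts = [int(c) for c in counts]
    if not counts:
        raise ValueError("counts must be non-empty")
    if any(c < 1 for c in counts):
        raise ValueError("all counts must be >= 1 (drop absent taxa first)")
    return counts


def chao1(counts: Sequence[int], bias_corrected: bool = True) -> float:
    """Chao1 richness estimate.

    Bias-corrected form (default): S_obs + F1(F1-1) / (2(F2+1)).
    Classic form: S_obs + F1^2 / (2 F2), falling back to the corrected
    form when there are no doubletons.
    """
    counts = _validate(counts)
    s_obs = len(counts)
    f1 = counts.count(1)
    f2 = counts.count(2)
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    return s_obs + f1 * f1 / (2 * f2)


def ace(counts: Sequence[int], rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    S_abund + S_rare / C_ace + (F1 / C_ace) * gamma^2, where the rare class
    is counts <= ``rare_threshold``, C_ace = 1 - F1/N_rare is the rare-class
    sample coverage and gamma^2 the rare-class coefficient of variation.
    When every rare individual is a singleton C_ace is zero and the
    estimator is undefined; Chao1 is returned with a warning.
    """
    counts = _validate(counts)
    rare = [c for c in counts if c <= rare_threshold]
    s_abund = len(counts) - len(rare)
    if not rare:
        return float(len(counts))
    s_rare = len(rare)
    n_rare = sum(rare)
    f1 = rare.count(1)
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn(
            "ACE undefined (all rare individuals are singletons); falling back to Chao1",
            stacklevel=2,
        )
        return chao1(counts)
    freqs = Counter(rare)
    sum_i = sum(i * (i - 1) * f for i, f in freqs.items())
    gamma2 = max((s_rare / c_ace) * sum_i / (n_rare * (n_rare - 1)) - 1.0, 0.0) if n_rare > 1 else 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def shannon(counts: Sequence[int], base: float = math.e) -> float:
    """Shannon diversity, -sum p_i log_base p_i (natural log by default)."""
    counts = _validate(counts)
    n = sum(counts)
    return -sum((c / n) * math.log(c / n, base) for c in counts)


def simpson(counts: Sequence[int]) -> float:
    """Simpson diversity, 1 - sum p_i^2 (probability two draws differ)."""
    counts = _validate(counts)
    n = sum(counts)
    return 1.0 - sum((c / n) ** 2 for c in counts)


def goods_coverage(counts: Sequence[int]) -> float:
    """Good's coverage as a percentage, 100 (1 - F1/N)."""
    counts = _validate(counts)
    return 100.0 * (1.0 - counts.count(1) / sum(counts))


def alpha_summary(
    samples: dict[str, Sequence[int]],
    shannon_base: float = math.e,
    ace_rare_threshold: int = 10,
    chao1_bias_corrected: bool = True,
) -> pd.DataFrame:
    """Tabulate all indices for a set of labelled abundance vectors."""
    rows = []
    for label, counts in samples.items():
        rows.append(
            {
                "label": label,
                "n_otus": len(list(counts)),
                "total": sum(counts),
                "coverage_percent": goods_coverage(counts),
                "chao1": chao1(counts, bias_corrected=chao1_bias_corrected),
                "ace": ace(counts, rare_threshold=ace_rare_threshold),
                "shannon": shannon(counts, base=shannon_base),
                "simpson": simpson(counts),
            }
        )
    return pd.DataFrame(rows)
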