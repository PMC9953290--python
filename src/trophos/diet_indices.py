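"""Stomach-content diet statistics.

Implements the classical trophic indices used in fish diet studies:

* stomach fullness (content weight as % of body weight, a feeding-intensity
  proxy),
* percentage frequency of occurrence ``%F``, numeric composition ``%N``,
  gravimetric composition ``%W``,
* the index of relative importance ``IRI = (%N + %W) x %F`` and its
  normalized percentage ``%IRI`` (Pinkas convention),
* Shannon–Wiener diet diversity H' per stomach and pooled per group.

``%N`` follows the standard count-based numeric composition
(``c_i * 100 / C_tot``), mirroring the gravimetric index.  ``%F`` counts
occurrences against all examined stomachs by default (including empty
ones); pass ``nonempty_only=True`` to restrict the denominator.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, EmptyGroupError
from .types import StomachSample

logger = logging.getLogger(__name__)

__all__ = [
    "stomach_fullness",
    "diet_index_table",
    "shannon_diversity",
    "pooled_shannon",
    "biomass_matrix",
]


def stomach_fullness(content_weight_g: float, body_weight_g: float) -> float:
    """Stomach fullness: content weight / body weight x 100 (percent).

    Raises
    ------
    DomainError
        If body weight is non-positive or content weight negative.
    """
    if body_weight_g <= 0:
        raise DomainError(f"body weight must be positive, got {body_weight_g}")
    if content_weight_g < 0:
        raise DomainError(f"content weight must be >= 0, got {content_weight_g}")
    return 100.0 * content_weight_g / body_weight_g


def _effective_count(record) -> int:
    """Count used for %N; unidentifiable fragments weighed but not counted
    enter as one individual."""
    if record.count == 0 and record.weight_g > 0:
        logger.debug(
            "prey %r has weight but zero count; treating count as 1", record.taxon
        )
        return 1
    return record.count


def diet_index_table(
    stomachs: Sequence[StomachSample],
    include_other: bool = False,
    nonempty_only: bool = False,
) -> pd.DataFrame:
    """Per-taxon diet indices for one group of stomachs.

    Parameters
    ----------
    stomachs
        Stomachs of one group (e.g. one species in one area).
    include_other
        Keep non-prey material (scales, parasites, undigested matter) in
        the computation.  Diet-composition analyses drop it.
    nonempty_only
        Use only non-empty stomachs as the ``%F`` denominator instead of
        all examined stomachs.

    Returns
    -------
    DataFrame indexed by taxon with columns ``n_occurrence, F_pct, N_pct,
    W_pct, IRI, IRI_pct``, sorted by descending ``IRI_pct``.

    Raises
    ------
    EmptyGroupError
        If no stomach in the group holds a (retained) prey record.
    DomainError
        On negative prey weights.
    """
    n_examined = len(stomachs) if not nonempty_only else sum(
        1 for s in stomachs if not s.empty
    )
    occurrence: dict[str, int] = {}
    counts: dict[str, int] = {}
    weights: dict[str, float] = {}
    for st in stomachs:
        seen = set()
        for p in st.prey:
            if p.is_other and not include_other:
                continue
            if p.weight_g < 0:
                raise DomainError("negative prey weight")
            if p.taxon not in seen:
                occurrence[p.taxon] = occurrence.get(p.taxon, 0) + 1
                seen.add(p.taxon)
            counts[p.taxon] = counts.get(p.taxon, 0) + _effective_count(p)
            weights[p.taxon] = weights.get(p.taxon, 0.0) + p.weight_g

    if not occurrence or n_examined == 0:
        raise EmptyGroupError("no prey records in group (all stomachs empty?)")

    taxa = sorted(occurrence)
    c_tot = sum(counts.values())
    w_tot = sum(weights.values())
    if c_tot == 0:
        raise EmptyGroupError("total prey count is zero")
    if w_tot == 0:
        raise EmptyGroupError("total prey weight is zero")

    tab = pd.DataFrame(index=pd.Index(taxa, name="taxon"))
    tab["n_occurrence"] = [occurrence[t] for t in taxa]
    tab["F_pct"] = tab["n_occurrence"] * 100.0 / n_examined
    tab["N_pct"] = [counts[t] * 100.0 / c_tot for t in taxa]
    tab["W_pct"] = [weights[t] * 100.0 / w_tot for t in taxa]
    tab["IRI"] = (tab["N_pct"] + tab["W_pct"]) * tab["F_pct"]
    tab["IRI_pct"] = tab["IRI"] * 100.0 / tab["IRI"].sum()
    return tab.sort_values("IRI_pct", ascending=False)


def shannon_diversity(
    stomach: StomachSample,
    basis: str = "count",
    include_other: bool = True,
) -> float:
    """Shannon–Wiener diversity H' = -sum p_i ln p_i of one stomach.

    ``basis`` selects the abundance measure for ``p_i``: prey counts
    (default, i.e. numbers of individuals) or ``"biomass"`` (weights).

    Raises
    ------
    EmptyGroupError
        If the stomach holds no prey individuals (H' undefined).
    """
    if basis not in ("count", "biomass"):
        raise DomainError(f"unknown basis {basis!r}")
    vals = []
    for p in stomach.prey:
        if p.is_other and not include_other:
            continue
        vals.append(float(_effective_count(p)) if basis == "count" else p.weight_g)
    total = sum(vals)
    if total <= 0:
        raise EmptyGroupError("diversity undefined: no prey individuals")
    h = 0.0
    for v in vals:
        if v > 0:
            pi = v / total
            h -= pi * math.log(pi)
    return h


def pooled_shannon(
    stomachs: Iterable[StomachSample],
    basis: str = "count",
    include_other: bool = True,
) -> float:
    """H' over the pooled prey abundances of a whole group of stomachs."""
    pooled: dict[str, float] = {}
    for st in stomachs:
        for p in st.prey:
            if p.is_other and not include_other:
                continue
            v = float(_effective_count(p)) if basis == "count" else p.weight_g
            pooled[p.taxon] = pooled.get(p.taxon, 0.0) + v
    total = sum(pooled.values())
    if total <= 0:
        raise EmptyGroupError("diversity undefined: no prey individuals")
    arr = np.array([v for v in pooled.values() if v > 0]) / total
    return float(-(arr * np.log(arr)).sum())


def biomass_matrix(
    stomachs: Sequence[StomachSample],
    include_other: bool = False,
    drop_empty: bool = True,
) -> pd.DataFrame:
    """Samples x taxa prey-biomass matrix (grams) for multivariate analysis.

    Empty stomachs are dropped by default; "other" material is excluded,
    matching how the diet-composition resemblance matrices are built.
    """
    rows: dict[str, dict[str, float]] = {}
    taxa: set[str] = set()
    for st in stomachs:
        if drop_empty and st.empty:
            continue
        row: dict[str, float] = {}
        for p in st.prey:
            if p.is_other and not include_other:
                continue
            row[p.taxon] = row.get(p.taxon, 0.0) + p.weight_g
            taxa.add(p.taxon)
        rows[st.specimen_id] = row
    cols = sorted(taxa)
    mat = pd.DataFrame(
        [[rows[sid].get(t, 0.0) for t in cols] for sid in rows],
        index=pd.Index(list(rows), name="specimen_id"),
        columns=cols,
    )
    return mat
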