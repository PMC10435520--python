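"""Labelling statistics computed from corrected MIDs.

The readouts implemented here are the working vocabulary of 13C tracing in
central carbon metabolism:

* fraction of enrichment — the summed fraction of isotopologues m+2 and
  above, the conservative "pathway-derived" labelling readout (m+1 species
  are dominated by residual natural abundance and single-carbon exchange);
* the m+3/m+2 ratio in malate, citrate and aspartate — the relative
  activity of pyruvate carboxylase (PC; anaplerotic, contributes 3 labelled
  carbons from 13C3 pyruvate) versus pyruvate dehydrogenase (PDH;
  oxidative, contributes 2 via acetyl-CoA);
* PC activity — the m+3 fraction itself, read in aspartate as a proxy for
  the oxaloacetate pool;
* carbon-pool contribution — isotopologue fractions weighted by the share
  of carbons they label, sum_i (i/n) m_i, merged across parallel glucose /
  glutamine / palmitate tracer cultures into nutrient-contribution
  profiles.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .isotope import MetaboliteDef, MIDVector

__all__ = [
    "fraction_enrichment",
    "labelled_fraction",
    "pc_pdh_ratio",
    "pc_activity",
    "carbon_pool_contribution",
    "merge_nutrient_contributions",
    "enrichment_table",
    "anaplerosis_table",
    "contribution_table",
    "nutrient_contribution_profile",
    "TRACERS",
]

TRACERS = ("glucose", "glutamine", "palmitate")

#: Metabolites whose m+3/m+2 ratio reads PC vs PDH activity.
PC_PDH_METABOLITES = ("malate", "citrate", "aspartate")


def fraction_enrichment(mid: MIDVector) -> float:
    """Summed fraction of isotopologues m+2 and above (0 when n < 2)."""
    return float(mid.fractions[2:].sum())


def labelled_fraction(mid: MIDVector) -> float:
    """1 − m0: any-label fraction, a diagnostics companion to enrichment."""
    return float(1.0 - mid.fractions[0])


def pc_pdh_ratio(mid: MIDVector) -> float:
    """m+3 / m+2 — relative pyruvate carboxylase vs dehydrogenase activity.

    Returns NaN (flagged undefined) when m+2 = 0; requires >= 3 carbons.
    Intended for malate, citrate and aspartate.
    """
    if mid.n_carbons < 3:
        raise ValueError(
            f"{mid.metabolite.name}: pc_pdh_ratio needs >= 3 carbons"
        )
    m2, m3 = mid[2], mid[3]
    if m2 == 0:
        return float("nan")
    return m3 / m2


def pc_activity(mid: MIDVector) -> float:
    """m+3 fraction — the direct pyruvate-carboxylase labelling readout.

    Conventionally read in aspartate (oxaloacetate proxy); any metabolite
    with >= 3 carbons is accepted with a warning.
    """
    if mid.n_carbons < 3:
        raise ValueError(f"{mid.metabolite.name}: pc_activity needs >= 3 carbons")
    if mid.metabolite.name != "aspartate":
        warnings.warn(
            f"pc_activity conventionally read in aspartate, got "
            f"{mid.metabolite.name}",
            stacklevel=2,
        )
    return mid[3]


def carbon_pool_contribution(mid: MIDVector) -> float:
    """Fraction of the metabolite's carbon atoms derived from the tracer.

    Each isotopologue is weighted by the number of carbons it contributes:
    sum_i (i/n) m_i.  An m+5 glutamate molecule contributes more carbon
    than an m+3 one, which plain fractional labelling ignores.
    """
    n = mid.n_carbons
    weights = np.arange(n + 1) / n
    return float(np.dot(weights, mid.fractions))


def merge_nutrient_contributions(
    contributions: Mapping[str, float],
    tracers: Iterable[str] = TRACERS,
) -> dict[str, float]:
    """Merge per-tracer mean carbon contributions into one profile.

    ``contributions`` maps tracer name -> mean carbon_pool_contribution for
    one metabolite (tracers are parallel cultures of the same condition, so
    means are merged, never per-sample values across tracers).  The
    complement is reported as ``unassigned``; if the tracer sum exceeds 1
    (cross-talk/noise), unassigned is clamped to 0 and the overshoot is
    surfaced in ``excess`` rather than hidden.  Missing tracers are
    tolerated with a warning — unassigned absorbs them.
    """
    tracers = tuple(tracers)
    missing = [t for t in tracers if t not in contributions]
    if missing:
        warnings.warn(
            f"tracer(s) {missing} not measured; unassigned fraction absorbs "
            "their contribution",
            stacklevel=2,
        )
    profile = {t: float(contributions.get(t, 0.0)) for t in tracers}
    total = sum(profile.values())
    profile["unassigned"] = max(0.0, 1.0 - total)
    profile["excess"] = max(0.0, total - 1.0)
    return profile


# ---------------------------------------------------------------------------
# Table-level interface (long corrected table + sample metadata)
# ---------------------------------------------------------------------------


def _iter_mids(corrected: pd.DataFrame, registry: Mapping[str, MetaboliteDef]):
    for (sample, met), grp in corrected.groupby(
        ["sample_id", "metabolite"], sort=True
    ):
        mdef = registry[met]
        fr = np.zeros(mdef.n_carbons + 1)
        fr[grp["iso_index"].to_numpy()] = grp["fraction_corrected"].to_numpy()
        yield sample, met, MIDVector(mdef, fr / fr.sum())


def enrichment_table(
    corrected: pd.DataFrame, registry: Mapping[str, MetaboliteDef]
) -> pd.DataFrame:
    """Per sample x metabolite fractional-enrichment table."""
    rows = [
        {
            "sample_id": s,
            "metabolite": met,
            "fraction_enrichment": fraction_enrichment(mid),
            "labelled_fraction": labelled_fraction(mid),
        }
        for s, met, mid in _iter_mids(corrected, registry)
    ]
    return pd.DataFrame(rows)


def anaplerosis_table(
    corrected: pd.DataFrame,
    registry: Mapping[str, MetaboliteDef],
    metabolites: Iterable[str] = PC_PDH_METABOLITES,
) -> pd.DataFrame:
    """Per sample m+3/m+2 (PC/PDH) ratios for the indicated metabolites.

    Undefined ratios (m+2 = 0) propagate as NaN and are counted in a
    warning, never coerced to 0 or infinity.
    """
    wanted = set(metabolites)
    rows = []
    n_undef = 0
    for s, met, mid in _iter_mids(corrected, registry):
        if met not in wanted:
            continue
        ratio = pc_pdh_ratio(mid)
        if np.isnan(ratio):
            n_undef += 1
        rows.append(
            {
                "sample_id": s,
                "metabolite": met,
                "m2": mid[2],
                "m3": mid[3],
                "pc_pdh_ratio": ratio,
            }
        )
    if n_undef:
        warnings.warn(
            f"{n_undef} undefined pc_pdh_ratio value(s) (m+2 = 0) flagged as "
            "NaN",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def contribution_table(
    corrected: pd.DataFrame,
    registry: Mapping[str, MetaboliteDef],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Per sample x metabolite carbon-pool contribution, tagged by tracer.

    ``metadata`` must carry ``sample_id`` and ``tracer`` columns.
    """
    tracer_of = metadata.set_index("sample_id")["tracer"]
    rows = []
    for s, met, mid in _iter_mids(corrected, registry):
        if s not in tracer_of.index:
            raise ValueError(f"sample {s!r} missing from metadata")
        rows.append(
            {
                "sample_id": s,
                "metabolite": met,
                "tracer": tracer_of[s],
                "carbon_contribution": carbon_pool_contribution(mid),
            }
        )
    return pd.DataFrame(rows)


def nutrient_contribution_profile(
    contributions: pd.DataFrame,
    group_cols: Iterable[str] = ("metabolite", "condition"),
    tracers: Iterable[str] = TRACERS,
) -> pd.DataFrame:
    """Stacked nutrient-contribution profile per metabolite (x condition).

    Averages carbon contributions per tracer within each group (parallel
    cultures), then merges with the clamped-unassigned rule of
    :func:`merge_nutrient_contributions`.
    """
    group_cols = list(group_cols)
    means = (
        contributions.groupby(group_cols + ["tracer"], sort=True)[
            "carbon_contribution"
        ]
        .mean()
        .reset_index()
    )
    rows = []
    for key, grp in means.groupby(group_cols, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        per_tracer = dict(zip(grp["tracer"], grp["carbon_contribution"]))
        profile = merge_nutrient_contributions(per_tracer, tracers)
        rows.append({**dict(zip(group_cols, key)), **profile})
    return pd.DataFrame(rows)
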