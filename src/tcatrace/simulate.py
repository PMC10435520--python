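"""Single-turn TCA-cycle labelling simulator with known ground truth.

The generator produces isotopologue data whose true MIDs are closed-form
functions of a small set of flux-mixing fractions, so every downstream
stage (natural-abundance correction, enrichment statistics, differential
testing) can be verified against known answers.

Model (one turn of the cycle, no multi-turn recycling):

* uniformly 13C6 glucose labels a fraction ``g_label`` of the pyruvate
  pool at m+3; lactate and alanine mirror pyruvate;
* pyruvate dehydrogenase (PDH) makes acetyl-CoA m+2 with probability
  ``f_pdh * g_label`` (fatty-acid oxidation of 13C16 palmitate makes it
  m+2 with probability ``f_fao`` under the palmitate tracer);
* pyruvate carboxylase (PC) makes oxaloacetate m+3 with probability
  ``f_pc * g_label``;
* citrate is the condensation (vector convolution) of the oxaloacetate
  and acetyl-CoA moieties — its m+5 species exists only when PC-m+3 and
  PDH-m+2 condense, which is why m+5 collapses when PC is ablated;
* each decarboxylation (citrate 6C -> AKG 5C -> ... -> malate 4C) removes
  one uniformly chosen carbon: from m+k the product is m+(k−1) with
  probability k/n, else m+k (positional information is deliberately not
  claimed);
* glutamate exchanges with an unlabelled pool: ``d_exch`` is the diluted
  fraction; under the 13C5 glutamine tracer AKG is seeded m+5 with
  probability ``f_gln``;
* the malate/aspartate pool mixes fresh PC-derived oxaloacetate (weight
  ``f_pc``) with oxidatively derived carbon (weight ``1 − f_pc``).

Observation adds forward natural-abundance convolution, a random
per-(sample, metabolite) total-intensity scale, and multiplicative
log-normal noise per isotopologue.  All randomness flows from one seed
through named substreams, so regeneration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .isotope import (
    CorrectionSettings,
    MetaboliteDef,
    MIDVector,
    default_registry,
    na_correction_matrix,
)

__all__ = [
    "FluxScenario",
    "SimulatedDataset",
    "IMATINIB_LIKE_EFFECT",
    "simulate_mids",
    "observe",
    "generate_cohort",
    "write_dataset",
    "scenario_from_yaml",
    "MEASURED_METABOLITES",
]

#: Internal pool carbon counts (superset of the measurable panel).
_POOL_CARBONS = {
    "pyruvate": 3,
    "lactate": 3,
    "alanine": 3,
    "acetyl-CoA": 2,
    "oxaloacetate": 4,
    "citrate": 6,
    "alpha-ketoglutarate": 5,
    "glutamate": 5,
    "malate": 4,
    "aspartate": 4,
}

#: Metabolites emitted as measured peak-area records (all in the default
#: registry; acetyl-CoA and oxaloacetate stay internal).
MEASURED_METABOLITES = (
    "pyruvate",
    "lactate",
    "alanine",
    "citrate",
    "alpha-ketoglutarate",
    "glutamate",
    "malate",
    "aspartate",
)

_JITTERED_FIELDS = ("g_label", "f_pdh", "f_fao", "f_pc", "f_gln", "d_exch")

_TRACER_ABBREV = {"glucose": "glc", "glutamine": "gln", "palmitate": "palm"}

#: Default treated-arm effect: PDH flux reduced, glucose labelling mildly
#: reduced, PC flux untouched — the TKI-response pattern the simulator is
#: built to emulate.
IMATINIB_LIKE_EFFECT: dict[str, float] = {
    "f_pdh": 0.6,
    "g_label": 0.8,
    "f_pc": 1.0,
}


@dataclass(frozen=True)
class FluxScenario:
    """Ground-truth mixing fractions for one simulated culture.

    Defaults describe an actively glucose-oxidising progenitor-like state:
    most of the pyruvate pool labelled from 11 mM 13C6 glucose after 24 h,
    acetyl-CoA mostly from PDH with a substantial fatty-acid-oxidation
    share, a modest PC (anaplerotic) fraction, and visible glutaminolysis.
    Tracer concentrations (11 mM glucose, 2 mM glutamine, 100 uM palmitate)
    are metadata only — they do not enter the MID model.
    """

    g_label: float = 0.7
    f_pdh: float = 0.55
    f_fao: float = 0.25
    f_pc: float = 0.25
    f_gln: float = 0.6
    d_exch: float = 0.2
    tracer: str = "glucose"
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        violations = []
        for name in _JITTERED_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                violations.append(f"{name}={v} outside [0, 1]")
        if self.f_pdh + self.f_fao > 1.0 + 1e-12:
            violations.append(
                f"f_pdh + f_fao = {self.f_pdh + self.f_fao} > 1"
            )
        if self.noise_cv < 0:
            violations.append(f"noise_cv={self.noise_cv} < 0")
        if self.tracer not in ("glucose", "glutamine", "palmitate"):
            violations.append(f"unknown tracer {self.tracer!r}")
        if violations:
            raise ValueError("invalid scenario: " + "; ".join(violations))

    def replace(self, **kw) -> "FluxScenario":
        return dataclasses.replace(self, **kw)


def _e0(n: int) -> np.ndarray:
    v = np.zeros(n + 1)
    v[0] = 1.0
    return v


def _point(n: int, k: int, p: float) -> np.ndarray:
    """MID that is m+k with probability p, else m+0."""
    v = _e0(n) * (1.0 - p)
    v[k] += p
    return v


def convolve_mids(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """MID of a condensation product of two independent moieties."""
    return np.convolve(a, b)


def carbon_loss(mid: np.ndarray) -> np.ndarray:
    """Remove one uniformly chosen carbon (n+1-length MID -> n-length).

    From m+k the product is m+(k−1) with probability k/n (the lost carbon
    was labelled) and m+k otherwise.
    """
    n = mid.size - 1
    out = np.zeros(n)
    k = np.arange(n + 1)
    keep = mid * (n - k) / n  # product stays m+k (k <= n-1)
    drop = mid * k / n  # product is m+(k-1)
    out += keep[:n]
    out += drop[1:]
    return out


def simulate_mids(scenario: FluxScenario) -> dict[str, MIDVector]:
    """Noise-free ground-truth MIDs for every pool under the scenario."""
    g = scenario.g_label
    tr = scenario.tracer

    if tr == "glucose":
        pyr = _point(3, 3, g)
        acc = _point(2, 2, scenario.f_pdh * g)
        oaa_first = _point(4, 3, scenario.f_pc * g)
        oaa_pc = _point(4, 3, g)
    elif tr == "palmitate":
        pyr = _e0(3)
        acc = _point(2, 2, scenario.f_fao)
        oaa_first = _e0(4)
        oaa_pc = _e0(4)
    else:  # glutamine
        pyr = _e0(3)
        acc = _e0(2)
        oaa_first = _e0(4)
        oaa_pc = _e0(4)

    if tr == "glutamine":
        akg = _point(5, 5, scenario.f_gln)
        mal = scenario.f_pc * oaa_pc + (1 - scenario.f_pc) * carbon_loss(akg)
        # one turn forward from the glutamine entry point: the labelled
        # malate/OAA pool condenses with (unlabelled) acetyl-CoA
        cit = convolve_mids(mal, acc)
    else:
        cit = convolve_mids(oaa_first, acc)
        akg = carbon_loss(cit)
        mal = scenario.f_pc * oaa_pc + (1 - scenario.f_pc) * carbon_loss(akg)

    glu = (1 - scenario.d_exch) * akg + scenario.d_exch * _e0(5)

    pools = {
        "pyruvate": pyr,
        "lactate": pyr.copy(),
        "alanine": pyr.copy(),
        "acetyl-CoA": acc,
        "oxaloacetate": oaa_first,
        "citrate": cit,
        "alpha-ketoglutarate": akg,
        "glutamate": glu,
        "malate": mal,
        "aspartate": mal.copy(),
    }
    registry = default_registry()
    out = {}
    for name, fr in pools.items():
        n = _POOL_CARBONS[name]
        mdef = registry.get(name, MetaboliteDef(name, n))
        out[name] = MIDVector(mdef, fr)
    return out


def observe(
    true_mids: Mapping[str, MIDVector],
    scenario: FluxScenario,
    sample_id: str = "S1",
    settings: CorrectionSettings | None = None,
    rng: np.random.Generator | None = None,
    base_intensity: float = 1e6,
    metabolites: tuple[str, ...] = MEASURED_METABOLITES,
) -> pd.DataFrame:
    """Forward-model measured isotopologue peak areas for one sample.

    True MIDs are convolved with natural abundance (matrix product with
    :func:`na_correction_matrix`), scaled by a random total intensity per
    metabolite, and each isotopologue multiplied by log-normal noise with
    coefficient of variation ``scenario.noise_cv``.
    """
    settings = settings or CorrectionSettings()
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    sigma = float(np.sqrt(np.log1p(scenario.noise_cv**2)))
    rows = []
    for met in metabolites:
        mid = true_mids[met]
        n = mid.n_carbons
        measured = na_correction_matrix(n, settings) @ mid.fractions
        scale = base_intensity * rng.lognormal(0.0, 0.25)
        noise = (
            rng.lognormal(0.0, sigma, size=n + 1) if sigma > 0 else np.ones(n + 1)
        )
        areas = scale * measured * noise
        for i in range(n + 1):
            rows.append((sample_id, met, i, areas[i]))
    return pd.DataFrame(
        rows, columns=["sample_id", "metabolite", "iso_index", "peak_area"]
    )


@dataclass
class SimulatedDataset:
    """A paired cohort with full ground-truth provenance."""

    measured: pd.DataFrame
    metadata: pd.DataFrame
    true_mids: dict[str, dict[str, list[float]]]
    scenarios: dict[str, FluxScenario]
    cell_counts: pd.DataFrame
    medium: pd.DataFrame
    control_scenario: FluxScenario
    effect: dict[str, float]
    seed: int

    def truth_dict(self) -> dict:
        return {
            "seed": self.seed,
            "control_scenario": dataclasses.asdict(self.control_scenario),
            "effect": self.effect,
            "scenarios": {
                s: dataclasses.asdict(sc) for s, sc in self.scenarios.items()
            },
            "true_mids": self.true_mids,
        }


def _jitter_scenario(
    base: FluxScenario, rng: np.random.Generator, cv: float
) -> FluxScenario:
    """Subject-level log-normal jitter of the mixing fractions, clipped."""
    sigma = float(np.sqrt(np.log1p(cv**2)))
    kw = {}
    for name in _JITTERED_FIELDS:
        v = getattr(base, name) * rng.lognormal(0.0, sigma)
        kw[name] = float(np.clip(v, 0.0, 1.0))
    tot = kw["f_pdh"] + kw["f_fao"]
    if tot > 1.0:
        kw["f_pdh"] /= tot
        kw["f_fao"] /= tot
    return base.replace(**kw)


def _apply_effect(sc: FluxScenario, effect: Mapping[str, float]) -> FluxScenario:
    kw = {}
    for name, delta in effect.items():
        if name not in _JITTERED_FIELDS:
            raise ValueError(f"effect on unknown scenario field {name!r}")
        if delta < 0:
            raise ValueError(f"effect delta for {name} must be >= 0")
        kw[name] = float(np.clip(getattr(sc, name) * delta, 0.0, 1.0))
    sc = sc.replace(**kw)
    if sc.f_pdh + sc.f_fao > 1.0:
        tot = sc.f_pdh + sc.f_fao
        sc = sc.replace(f_pdh=sc.f_pdh / tot, f_fao=sc.f_fao / tot)
    return sc


#: Cell-free medium composition used for the matched spent-medium tables
#: (mM; 11 mM glucose and 2 mM glutamine, lactate/glutamate initially 0).
_CELLFREE_MM = {"glucose": 11.0, "glutamine": 2.0, "lactate": 0.0,
                "glutamate": 0.0}


def generate_cohort(
    n_pairs: int = 4,
    control_scenario: FluxScenario | None = None,
    effect: Mapping[str, float] | None = None,
    between_subject_cv: float = 0.15,
    seed: int = 0,
    settings: CorrectionSettings | None = None,
    tracers: tuple[str, ...] = ("glucose", "glutamine", "palmitate"),
) -> SimulatedDataset:
    """Simulate a paired control/treated cohort with matched ancillary data.

    Each of ``n_pairs`` subjects gets a jittered subject-level scenario;
    the treated arm applies multiplicative ``effect`` deltas (default
    :data:`IMATINIB_LIKE_EFFECT`; pass ``{}`` for a null cohort).  Every
    subject x arm is cultured in parallel under each tracer, and matched
    cell counts and spent-medium concentrations (consumption scaling with
    the subject's glucose labelling and glutaminolysis fractions) are
    emitted alongside the isotopologue tables.  The default cohort size
    matches a four-patient paired design.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    control_scenario = control_scenario or FluxScenario()
    effect = dict(IMATINIB_LIKE_EFFECT) if effect is None else dict(effect)
    settings = settings or CorrectionSettings()

    ss = np.random.SeedSequence(seed)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    noise_ss = ss.spawn(n_pairs * len(tracers) * 2 + 1)
    aux_rng = np.random.default_rng(noise_ss[-1])

    measured_parts: list[pd.DataFrame] = []
    meta_rows, cc_rows, medium_rows = [], [], []
    true_mids: dict[str, dict[str, list[float]]] = {}
    scenarios: dict[str, FluxScenario] = {}

    stream = 0
    half = (n_pairs + 1) // 2
    for i in range(1, n_pairs + 1):
        pair_id = f"P{i:02d}"
        batch = "B1" if i <= half else "B2"
        subject = _jitter_scenario(control_scenario, jitter_rng, between_subject_cv)
        arms = {"control": subject, "treated": _apply_effect(subject, effect)}
        for cond, sc_arm in arms.items():
            # growth: controls roughly quadruple over 48 h, treated slower
            growth = (4.0 if cond == "control" else 3.2) * aux_rng.lognormal(
                0.0, 0.1
            )
            cells_d0 = 4e5
            cells_d2 = cells_d0 * growth
            for tracer in tracers:
                sc = sc_arm.replace(tracer=tracer)
                sample_id = f"{pair_id}_{cond}_{_TRACER_ABBREV[tracer]}"
                mids = simulate_mids(sc)
                rng = np.random.default_rng(noise_ss[stream])
                stream += 1
                measured_parts.append(
                    observe(mids, sc, sample_id, settings, rng)
                )
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "condition": cond,
                        "pair_id": pair_id,
                        "batch": batch,
                        "tracer": tracer,
                    }
                )
                true_mids[sample_id] = {
                    m: mids[m].fractions.tolist() for m in mids
                }
                scenarios[sample_id] = sc
                cc_rows.append(
                    {
                        "sample_id": sample_id,
                        "cells_d0": cells_d0,
                        "cells_d2": cells_d2,
                    }
                )
            # one spent-medium panel per subject x arm (culture-level)
            glc_consumed = 5.0 * sc_arm.g_label
            gln_consumed = 1.2 * sc_arm.f_gln
            spent = {
                "glucose": max(0.0, _CELLFREE_MM["glucose"] - glc_consumed),
                "lactate": 1.7 * glc_consumed,
                "glutamine": max(0.0, _CELLFREE_MM["glutamine"] - gln_consumed),
                "glutamate": 0.05 * gln_consumed,
            }
            for met, conc in spent.items():
                medium_rows.append(
                    {
                        "sample_id": f"{pair_id}_{cond}",
                        "condition": cond,
                        "pair_id": pair_id,
                        "metabolite": met,
                        "conc_spent": conc,
                        "conc_cellfree": _CELLFREE_MM[met],
                        "cells_d0": cells_d0,
                        "cells_d2": cells_d2,
                    }
                )

    return SimulatedDataset(
        measured=pd.concat(measured_parts, ignore_index=True),
        metadata=pd.DataFrame(meta_rows),
        true_mids=true_mids,
        scenarios=scenarios,
        cell_counts=pd.DataFrame(cc_rows),
        medium=pd.DataFrame(medium_rows),
        control_scenario=control_scenario,
        effect=effect,
        seed=seed,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write a cohort in the file formats the analysis pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.measured.to_csv(outdir / "isotopologues.csv", index=False)
    ds.metadata.to_csv(outdir / "metadata.csv", index=False)
    ds.cell_counts.to_csv(outdir / "cell_counts.csv", index=False)
    ds.medium.to_csv(outdir / "medium.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(ds.truth_dict(), fh, indent=1, sort_keys=True)


def scenario_from_yaml(path: str | Path) -> FluxScenario:
    """Load a :class:`FluxScenario` from a YAML mapping of field -> value."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"scenario file {path}: expected a mapping")
    unknown = set(raw) - {f.name for f in dataclasses.fields(FluxScenario)}
    if unknown:
        raise ValueError(f"scenario file {path}: unknown fields {sorted(unknown)}")
    return FluxScenario(**raw)
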