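"""Carbon isotopologue bookkeeping and natural-abundance correction.

A metabolite with *n* carbon atoms measured by LC-MS yields *n* + 1
isotopologue peaks m+0 … m+n, where m+i is the species carrying i heavy
(13C) carbons.  The normalised vector of those peak fractions is the mass
isotopomer distribution (MID).  Because ~1.07 % of natural carbon is 13C,
the *measured* MID is a smeared version of the tracer-derived MID: each
molecule with j tracer-labelled carbons is detected at m+i (i >= j) with
probability given by a binomial draw over its n − j unlabelled positions.

This module builds that (lower-triangular, column-stochastic) smearing
matrix, inverts it to recover tracer-only MIDs, and provides the plumbing
to turn long-format peak-area tables into corrected fraction tables.

Only carbon is corrected: the analysis tracks 13C isotopologues resolved by
unit mass on an Orbitrap, so the correction matrix stays exactly binomial.
An optional tracer-purity factor (a second binomial over the *labelled*
carbons) models incompletely enriched tracer substrates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import nnls
from scipy.stats import binom

__all__ = [
    "MetaboliteDef",
    "MIDVector",
    "RawIsotopologueRecord",
    "CorrectionSettings",
    "parse_formula",
    "na_correction_matrix",
    "correct_natural_abundance",
    "mid_from_intensities",
    "default_registry",
    "load_registry",
    "read_isotopologue_table",
    "correct_table",
    "NATURAL_13C_ABUNDANCE",
]

#: IUPAC representative natural abundance of 13C.
NATURAL_13C_ABUNDANCE = 0.0107

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U".split()
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed or chemically invalid elemental formula."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula into element -> count.

    An omitted count means 1 ("C5H9NO4" -> N:1).  Explicit zero counts and
    unknown element symbols are rejected.
    """
    if not formula or not isinstance(formula, str):
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(
                f"unparseable token {formula[pos:m.start()]!r} in {formula!r}"
            )
        pos = m.end()
        elem, digits = m.groups()
        if elem not in _ELEMENTS:
            raise FormulaError(f"unknown element symbol {elem!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + n
    if pos != len(formula):
        raise FormulaError(f"unparseable token {formula[pos:]!r} in {formula!r}")
    return counts


@dataclass(frozen=True)
class MetaboliteDef:
    """A metabolite identity fixing the MID length via its carbon count."""

    name: str
    n_carbons: int
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"{self.name}: n_carbons must be >= 1")
        if self.formula is not None:
            n_c = parse_formula(self.formula).get("C", 0)
            if n_c != self.n_carbons:
                raise ValueError(
                    f"{self.name}: formula {self.formula} has {n_c} carbons, "
                    f"declared n_carbons={self.n_carbons}"
                )


_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MIDVector:
    """A mass isotopomer distribution m+0 … m+n for one metabolite.

    fractions[i] is the fraction of molecules carrying i heavy carbons;
    the vector has length n_carbons + 1 and sums to 1.
    """

    metabolite: MetaboliteDef
    fractions: np.ndarray

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", fr)
        n = self.metabolite.n_carbons
        if fr.shape != (n + 1,):
            raise ValueError(
                f"{self.metabolite.name}: MID length {fr.shape} != {(n + 1,)}"
            )
        if np.any(fr < -_SUM_TOL) or np.any(fr > 1 + _SUM_TOL):
            raise ValueError(f"{self.metabolite.name}: fractions outside [0, 1]")
        if abs(fr.sum() - 1.0) > _SUM_TOL:
            raise ValueError(
                f"{self.metabolite.name}: fractions sum to {fr.sum()}, not 1"
            )

    def __getitem__(self, i: int) -> float:
        return float(self.fractions[i])

    @property
    def n_carbons(self) -> int:
        return self.metabolite.n_carbons


@dataclass(frozen=True)
class RawIsotopologueRecord:
    """One measured isotopologue peak area (arbitrary LC-MS units)."""

    sample_id: str
    metabolite: str
    iso_index: int
    peak_area: float

    def __post_init__(self) -> None:
        if self.iso_index < 0:
            raise ValueError(f"iso_index {self.iso_index} < 0")
        if self.peak_area < 0:
            raise ValueError(f"peak_area {self.peak_area} < 0")


@dataclass(frozen=True)
class CorrectionSettings:
    """Parameters of the natural-abundance (and tracer-purity) correction.

    p13c : probability that one natural carbon is 13C (default IUPAC 0.0107)
    tracer_purity : isotopic enrichment of the labelled substrate (default 1)
    nonneg : fall back to non-negative least squares when the exact solve
        yields negative fractions, then renormalise
    """

    p13c: float = NATURAL_13C_ABUNDANCE
    tracer_purity: float = 1.0
    nonneg: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p13c < 0.5:
            raise ValueError(f"p13c={self.p13c} outside [0, 0.5)")
        if not 0.0 < self.tracer_purity <= 1.0:
            raise ValueError(f"tracer_purity={self.tracer_purity} outside (0, 1]")


def na_correction_matrix(
    n_carbons: int, settings: CorrectionSettings | None = None
) -> np.ndarray:
    """Forward natural-abundance smearing matrix for an n-carbon metabolite.

    Entry (i, j), i >= j, is the probability that a molecule with j
    tracer-labelled carbons is measured at m+i because of natural 13C in its
    n − j unlabelled carbons: C(n−j, i−j) p^(i−j) (1−p)^(n−j−(i−j)).  Columns
    are probability distributions and sum to 1.  When tracer purity < 1 a
    second binomial over the j nominally labelled carbons is composed in.
    Multiplying this matrix onto a true MID gives the measured MID; the
    correction is the inverse operation.
    """
    if n_carbons < 1:
        raise ValueError(f"n_carbons={n_carbons} must be >= 1")
    settings = settings or CorrectionSettings()
    n = n_carbons
    p = settings.p13c
    idx = np.arange(n + 1)
    # A[i, j] = Binom(n - j, p).pmf(i - j)
    i = idx[:, None]
    j = idx[None, :]
    a = binom.pmf(i - j, n - j, p)
    a = np.where(i >= j, a, 0.0)
    if settings.tracer_purity < 1.0:
        # U[k, j] = Binom(j, purity).pmf(k): j nominally labelled carbons,
        # each actually 13C with probability = purity.
        u = binom.pmf(i, j, settings.tracer_purity)
        u = np.where(i <= j, u, 0.0)
        a = a @ u
    return a


def _as_vector(measured: "MIDVector | np.ndarray | Sequence[float]") -> np.ndarray:
    if isinstance(measured, MIDVector):
        return np.asarray(measured.fractions, dtype=float)
    return np.asarray(measured, dtype=float)


def correct_natural_abundance(
    measured: "MIDVector | np.ndarray | Sequence[float]",
    metabolite: MetaboliteDef,
    settings: CorrectionSettings | None = None,
) -> MIDVector:
    """Deconvolve natural 13C abundance from a measured isotopologue vector.

    Solves M · x = measured for the tracer-only MID x, where M is
    :func:`na_correction_matrix`.  With ``settings.nonneg`` (the default) a
    negative exact solution triggers a non-negative least-squares refit;
    the result is renormalised to sum 1.  Raw (unnormalised) intensity
    vectors are accepted — the solution is scale-invariant.
    """
    settings = settings or CorrectionSettings()
    y = _as_vector(measured)
    n = metabolite.n_carbons
    if y.shape != (n + 1,):
        raise ValueError(
            f"{metabolite.name}: measured vector length {y.size} != {n + 1}"
        )
    if np.all(y == 0):
        raise ValueError(f"{metabolite.name}: no signal (all-zero input)")
    if np.any(y < 0):
        raise ValueError(f"{metabolite.name}: negative intensities")
    m = na_correction_matrix(n, settings)
    x = np.linalg.solve(m, y)
    scale = float(np.abs(x).max())
    if x.min() < -1e-10 * scale:
        if settings.nonneg:
            x, _ = nnls(m, y)
            if x.sum() == 0:
                raise ValueError(f"{metabolite.name}: degenerate NNLS solution")
        else:
            raise ValueError(
                f"{metabolite.name}: correction produced negative fractions "
                "(set nonneg=True to constrain the solve)"
            )
    x = np.clip(x, 0.0, None)
    x = x / x.sum()
    return MIDVector(metabolite, x)


def mid_from_intensities(
    records: Iterable[RawIsotopologueRecord] | Mapping[int, float],
    metabolite: MetaboliteDef,
) -> MIDVector:
    """Normalise peak areas for one sample x metabolite into an MID.

    Missing isotopologue indices are zero-filled with a warning (sparse
    detection at low abundance is routine); an all-zero total is an error.
    """
    n = metabolite.n_carbons
    areas = np.zeros(n + 1)
    seen: set[int] = set()
    if isinstance(records, Mapping):
        items = records.items()
    else:
        items = ((r.iso_index, r.peak_area) for r in records)
    for iso, area in items:
        if not 0 <= iso <= n:
            raise ValueError(
                f"{metabolite.name}: iso_index {iso} outside [0, {n}]"
            )
        if area < 0:
            raise ValueError(f"{metabolite.name}: negative peak area {area}")
        areas[iso] += area
        seen.add(iso)
    missing = sorted(set(range(n + 1)) - seen)
    if missing:
        warnings.warn(
            f"{metabolite.name}: isotopologue indices {missing} missing; "
            "zero-filled",
            stacklevel=2,
        )
    total = areas.sum()
    if total == 0:
        raise ValueError(f"{metabolite.name}: no signal (all-zero peak areas)")
    return MIDVector(metabolite, areas / total)


# ---------------------------------------------------------------------------
# Metabolite registry
# ---------------------------------------------------------------------------

_DEFAULT_PANEL: dict[str, tuple[int, str | None]] = {
    "pyruvate": (3, "C3H4O3"),
    "lactate": (3, "C3H6O3"),
    "alanine": (3, "C3H7NO2"),
    "serine": (3, "C3H7NO3"),
    "glycine": (2, "C2H5NO2"),
    "citrate": (6, "C6H8O7"),
    "alpha-ketoglutarate": (5, "C5H6O5"),
    "glutamate": (5, "C5H9NO4"),
    "glutamine": (5, "C5H10N2O3"),
    "malate": (4, "C4H6O5"),
    "aspartate": (4, "C4H7NO4"),
    "fumarate": (4, "C4H4O4"),
    "succinate": (4, "C4H6O4"),
    "glutathione": (10, "C10H17N3O6S"),
}


def default_registry() -> dict[str, MetaboliteDef]:
    """Carbon-count registry for the standard TCA/redox metabolite panel."""
    return {
        name: MetaboliteDef(name, n, f) for name, (n, f) in _DEFAULT_PANEL.items()
    }


def load_registry(path: str | Path) -> dict[str, MetaboliteDef]:
    """Load a metabolite registry from YAML.

    Accepted per-metabolite values: an integer carbon count, or a mapping
    with keys ``n_carbons`` and optional ``formula``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"registry {path}: expected a mapping")
    registry: dict[str, MetaboliteDef] = {}
    for name, val in raw.items():
        if isinstance(val, int):
            registry[name] = MetaboliteDef(name, val)
        elif isinstance(val, dict):
            registry[name] = MetaboliteDef(
                name, int(val["n_carbons"]), val.get("formula")
            )
        else:
            raise ValueError(f"registry {path}: bad entry for {name!r}: {val!r}")
    return registry


# ---------------------------------------------------------------------------
# Long-format table interface
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("sample_id", "metabolite", "iso_index", "peak_area")


def read_isotopologue_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format isotopologue table (comma or tab, auto-detected)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df["iso_index"] = df["iso_index"].astype(int)
    df["peak_area"] = df["peak_area"].astype(float)
    return df


def correct_table(
    df: pd.DataFrame,
    registry: Mapping[str, MetaboliteDef] | None = None,
    settings: CorrectionSettings | None = None,
) -> pd.DataFrame:
    """Natural-abundance correct a long-format isotopologue table.

    Returns the same long format with a ``fraction_corrected`` column, in
    deterministic (sample, metabolite, iso_index) order.  Metabolites absent
    from the registry are an error; sample x metabolite groups with no
    signal are dropped with a warning.
    """
    registry = registry or default_registry()
    settings = settings or CorrectionSettings()
    missing = sorted(set(df["metabolite"]) - set(registry))
    if missing:
        raise ValueError(f"metabolites not in registry: {missing}")
    out_rows: list[pd.DataFrame] = []
    dropped = 0
    for (sample, met), grp in df.groupby(["sample_id", "metabolite"], sort=True):
        mdef = registry[met]
        areas = dict(zip(grp["iso_index"], grp["peak_area"]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mid = mid_from_intensities(areas, mdef)
            corrected = correct_natural_abundance(mid, mdef, settings)
        except ValueError:
            dropped += 1
            continue
        out_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "metabolite": met,
                    "iso_index": np.arange(mdef.n_carbons + 1),
                    "fraction_measured": mid.fractions,
                    "fraction_corrected": corrected.fractions,
                }
            )
        )
    if dropped:
        warnings.warn(
            f"{dropped} sample x metabolite group(s) dropped (no signal)",
            stacklevel=2,
        )
    if not out_rows:
        raise ValueError("no correctable sample x metabolite groups in input")
    out = pd.concat(out_rows, ignore_index=True)
    return out.sort_values(
        ["sample_id", "metabolite", "iso_index"], kind="stable"
    ).reset_index(drop=True)
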