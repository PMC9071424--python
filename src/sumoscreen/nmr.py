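"""NMR titration mapping.

Classifies residues by titration-induced intensity loss or by combined
chemical-shift perturbation (CSP), using ordered threshold ladders: the most
affected bin is evaluated first and the first satisfied bin wins.  Eight
named ladders covering the supported titration designs ship as built-ins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, ValidationError

UNMEASURABLE = "unmeasurable"  # reference intensity <= 0 (grey)
UNASSIGNED = "unassigned"  # proline / never-assigned residue (black/grey)
UNCLASSIFIED = "unclassified"  # every ladder bin lacked its titration point


@dataclass
class TitrationSeries:
    """Per-residue observables across titration points.

    ``equivalents`` must start at 0 (the reference point) and be strictly
    increasing; observables are either ``intensities`` or ``shifts``
    (list of (dH, dN) ppm pairs), parallel to ``equivalents``.
    """

    residue: int
    aa: str
    equivalents: list[float]
    intensities: list[float] | None = None
    shifts: list[tuple[float, float]] | None = None
    assigned: bool = True

    def __post_init__(self) -> None:
        eq = np.asarray(self.equivalents, dtype=float)
        if eq.size == 0 or eq[0] != 0:
            raise ValidationError("titration point 0 must be the 0-equivalents reference")
        if np.any(np.diff(eq) <= 0):
            raise ValidationError("equivalents must be strictly increasing")
        obs = self.intensities if self.intensities is not None else self.shifts
        if obs is None or len(obs) != eq.size:
            raise ValidationError("one observable per titration point required")


@dataclass(frozen=True)
class LadderBin:
    """Ratio interval [lo, hi) evaluated at one titrant equivalents value."""

    equivalents: float
    lo: float
    hi: float


@dataclass
class GradientLadder:
    """Ordered intensity-ratio bins, rank 0 = most affected.

    Residues matching no bin get rank ``len(bins)`` (unaffected/blue).
    """

    name: str
    bins: list[LadderBin]
    colours: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.colours:
            self.colours = gradient_colours(len(self.bins) + 1)

    @property
    def n_ranks(self) -> int:
        return len(self.bins) + 1


@dataclass
class CspLadder:
    """Descending SD-multiple thresholds; rank 0 = multiple >= thresholds[0]."""

    name: str
    thresholds: list[float]
    colours: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.thresholds or not all(
            b < a for a, b in zip(self.thresholds, self.thresholds[1:])
        ):
            raise ValidationError("CSP thresholds must be strictly decreasing")
        if not self.colours:
            self.colours = gradient_colours(len(self.thresholds) + 1)

    @property
    def n_ranks(self) -> int:
        return len(self.thresholds) + 1


@dataclass
class CspRecord:
    residue: int
    csp: float
    sd_multiple: float = np.nan

    def __post_init__(self) -> None:
        if self.csp < 0:
            raise ValidationError("csp must be >= 0")


def gradient_colours(n: int) -> list[str]:
    """n hex colours interpolated red -> white -> blue (most -> least affected)."""
    if n == 1:
        return ["#FF0000"]
    out = []
    for i in range(n):
        t = i / (n - 1)
        if t <= 0.5:
            u = t / 0.5
            r, g, b = 255, int(255 * u), int(255 * u)
        else:
            u = (t - 0.5) / 0.5
            r, g, b = int(255 * (1 - u)), int(255 * (1 - u)), 255
        out.append(f"#{r:02X}{g:02X}{b:02X}")
    return out


def _interval_chain(equivalents: float, uppers: list[float]) -> list[LadderBin]:
    """Contiguous-from-zero bins [0,u1), [u1,u2), ... at one equivalents value."""
    bins, lo = [], 0.0
    for hi in uppers:
        bins.append(LadderBin(equivalents, lo, hi))
        lo = hi
    return bins


# Built-in ladders. Intensity designs use contiguous ratio intervals evaluated
# at the titration points of the corresponding experiment; CSP designs use
# SD-multiple thresholds.
BUILTIN_LADDERS: dict[str, GradientLadder | CspLadder] = {
    "xrcc4_msumo2": GradientLadder(
        "xrcc4_msumo2",
        _interval_chain(0.1, [0.45, 0.66])
        + _interval_chain(0.5, [0.45, 0.66])
        + _interval_chain(1.0, [0.45, 0.66])
        + _interval_chain(4.0, [0.45, 0.66]),
    ),
    "xrcc4_disumo2": GradientLadder(
        "xrcc4_disumo2",
        _interval_chain(0.125, [0.20, 0.30, 0.45, 0.66])
        + _interval_chain(0.25, [0.20, 0.30, 0.45, 0.66]),
    ),
    "xrcc4_4xsumo2": GradientLadder(
        "xrcc4_4xsumo2",
        _interval_chain(0.1, [0.20, 0.30, 0.45, 0.66])
        + _interval_chain(0.67, [0.20, 0.30, 0.45, 0.66]),
    ),
    "xrcc4_msumo1_csp": CspLadder("xrcc4_msumo1_csp", [5.0, 4.0, 3.0, 2.0, 1.0]),
    "msumo2_xrcc4": GradientLadder(
        "msumo2_xrcc4",
        _interval_chain(0.25, [0.20, 0.30, 0.40, 0.66])
        + _interval_chain(0.5, [0.20, 0.30, 0.40, 0.66]),
    ),
    "msumo2_xrcc4fl": GradientLadder(
        "msumo2_xrcc4fl", _interval_chain(0.33, [0.20, 0.30, 0.40, 0.66])
    ),
    "msumo2_pias2": GradientLadder(
        "msumo2_pias2", _interval_chain(0.5, [0.20, 0.30, 0.40, 0.66])
    ),
    "msumo1_xrcc4_csp": CspLadder("msumo1_xrcc4_csp", [4.0, 2.0, 1.0]),
}


def get_ladder(name: str) -> GradientLadder | CspLadder:
    try:
        return BUILTIN_LADDERS[name]
    except KeyError:
        raise ValidationError(
            f"unknown ladder '{name}'; built-ins: {', '.join(sorted(BUILTIN_LADDERS))}"
        ) from None


def load_ladder_config(path) -> GradientLadder | CspLadder:
    """Load a ladder from a key-value text file.

    Intensity ladders: ``bin = <equivalents> <lo> <hi>`` lines, most affected
    first.  CSP ladders: ``thresholds = 5 4 3 2 1``.  Optional ``name = ...``
    and ``colours = #RRGGBB #RRGGBB ...``.
    """
    name, bins, thresholds, colours = "custom", [], None, []
    with open(path, "rt") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "name":
                name = value
            elif key == "bin":
                e, lo, hi = (float(v) for v in value.split())
                bins.append(LadderBin(e, lo, hi))
            elif key == "thresholds":
                thresholds = [float(v) for v in value.split()]
            elif key == "colours":
                colours = value.split()
            else:
                raise ValidationError(f"unknown ladder config key '{key}'")
    if thresholds is not None and bins:
        raise ValidationError("ladder config mixes intensity bins and CSP thresholds")
    if thresholds is not None:
        return CspLadder(name, thresholds, colours)
    if not bins:
        raise ValidationError("ladder config defines no bins")
    return GradientLadder(name, bins, colours)


# ---------------------------------------------------------------------------
# Intensity classification
# ---------------------------------------------------------------------------

def intensity_ratios(series: TitrationSeries) -> dict[float, float] | None:
    """Per-point ratios I(e)/I(0), keyed by equivalents; None if I(0) <= 0."""
    if series.intensities is None:
        raise ValidationError("series carries no intensities")
    i0 = series.intensities[0]
    if i0 <= 0:
        return None
    return {
        e: i / i0 for e, i in zip(series.equivalents[1:], series.intensities[1:])
    }


def classify_ladder(ratios: dict[float, float], ladder: GradientLadder) -> int | None:
    """Rank of a residue's ratio vector: first satisfied bin, scanning from
    most affected; no match -> unaffected rank; all bins skipped for missing
    titration points -> None (unclassified)."""
    any_evaluated = False
    for rank, b in enumerate(ladder.bins):
        if b.equivalents not in ratios:
            continue
        any_evaluated = True
        if b.lo <= ratios[b.equivalents] < b.hi:
            return rank
    return ladder.n_ranks - 1 if any_evaluated else None


def classify_intensity_series(
    series_list: list[TitrationSeries], ladder: GradientLadder
) -> dict[int, int | str]:
    """Residue -> rank (or UNMEASURABLE / UNASSIGNED / UNCLASSIFIED marker)."""
    out: dict[int, int | str] = {}
    for s in series_list:
        if not s.assigned or s.aa == "P":
            out[s.residue] = UNASSIGNED
            continue
        ratios = intensity_ratios(s)
        if ratios is None:
            out[s.residue] = UNMEASURABLE
            continue
        rank = classify_ladder(ratios, ladder)
        out[s.residue] = UNCLASSIFIED if rank is None else rank
    return out


# ---------------------------------------------------------------------------
# CSP classification
# ---------------------------------------------------------------------------

N15_SCALING = 0.14


def csp(delta_h: float, delta_n: float, alpha: float = N15_SCALING) -> float:
    """Combined shift sqrt(dH^2 + (alpha * dN)^2) in ppm."""
    return float(np.sqrt(delta_h**2 + (alpha * delta_n) ** 2))


def mad_sd(values) -> float:
    """Robust SD estimate: 1.4826 x median absolute deviation."""
    v = np.asarray(values, dtype=float)
    return float(1.4826 * np.median(np.abs(v - np.median(v))))


def classify_csp(
    records: list[CspRecord], ladder: CspLadder, sd: float | str = "auto"
) -> dict[int, int]:
    """Residue -> rank by SD multiples of the combined shift.

    ``sd='auto'`` estimates the population SD as 1.4826 x MAD of the CSPs
    (needs >= 5 residues); boundary convention: a multiple equal to a
    threshold falls in the more-affected bin (>= at the top threshold).
    """
    if sd == "auto":
        if len(records) < 5:
            raise ValidationError("auto SD estimation needs at least 5 residues")
        sd = mad_sd([r.csp for r in records])
    sd = float(sd)
    if sd <= 0:
        raise DegenerateDataError("CSP standard deviation must be > 0")
    out = {}
    for r in records:
        r.sd_multiple = r.csp / sd
        rank = ladder.n_ranks - 1
        for i, thr in enumerate(ladder.thresholds):
            if r.sd_multiple >= thr:
                rank = i
                break
        out[r.residue] = rank
    return out


def series_to_csp_records(series_list: list[TitrationSeries], alpha: float = N15_SCALING,
                          point: int = -1) -> list[CspRecord]:
    """CSP of each residue between the reference and one titration point."""
    records = []
    for s in series_list:
        if s.shifts is None:
            raise ValidationError("series carries no chemical shifts")
        if not s.assigned or s.aa == "P":
            continue
        h0, n0 = s.shifts[0]
        h1, n1 = s.shifts[point]
        records.append(CspRecord(residue=s.residue, csp=csp(h1 - h0, n1 - n0, alpha)))
    return records


def rank_colour(rank: int | str, ladder: GradientLadder | CspLadder) -> str:
    if isinstance(rank, str):
        return {"unmeasurable": "#808080", "unassigned": "#000000",
                "unclassified": "#808080"}[rank]
    return ladder.colours[rank]


_PEAK_COLUMNS_INT = ("residue", "aa", "equivalents", "intensity")
_PEAK_COLUMNS_CSP = ("residue", "aa", "equivalents", "dH", "dN")


def read_peak_table(path) -> list[TitrationSeries]:
    """Read a CSV peak table into per-residue titration series.

    Columns: residue, aa, equivalents, intensity  (intensity mode), or
    residue, aa, equivalents, dH, dN  (shift mode).  An ``assigned`` column
    (0/1) is optional.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = set(df.columns)
    if set(_PEAK_COLUMNS_INT) <= cols:
        mode = "intensity"
    elif set(_PEAK_COLUMNS_CSP) <= cols:
        mode = "shift"
    else:
        raise ValidationError(
            "peak table needs columns (residue, aa, equivalents, intensity) "
            "or (residue, aa, equivalents, dH, dN)"
        )
    series = []
    for (res, aa), grp in df.groupby(["residue", "aa"], sort=True):
        grp = grp.sort_values("equivalents")
        assigned = bool(grp["assigned"].iloc[0]) if "assigned" in cols else True
        if mode == "intensity":
            series.append(
                TitrationSeries(
                    residue=int(res), aa=str(aa),
                    equivalents=grp["equivalents"].tolist(),
                    intensities=grp["intensity"].tolist(),
                    assigned=assigned,
                )
            )
        else:
            series.append(
                TitrationSeries(
                    residue=int(res), aa=str(aa),
                    equivalents=grp["equivalents"].tolist(),
                    shifts=list(zip(grp["dH"], grp["dN"])),
                    assigned=assigned,
                )
            )
    return series
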