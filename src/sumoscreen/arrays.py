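"""Protein-microarray hit calling.

Turns paired (probe-bound, mock) array scans into normalized M-values and a
receptor-candidate call set:

1. per-spot signal-to-noise, ``(F median - B median) / B SD``;
2. division by the median S/N of biological-control spots within each scan;
3. averaging of duplicate features;
4. log2 bound-minus-mock difference (M) against mean log-signal (A);
5. robust local-regression detrending of M, first per print-tip group
   (M vs A), then spatially over the whole slide (M vs x, y);
6. thresholding at population mean + k standard deviations.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import DegenerateDataError, FormatError, ValidationError

#: GPR column -> internal field name
GPR_COLUMNS = {
    "Block": "block_id",
    "Row": "row",
    "Column": "col",
    "X": "x",
    "Y": "y",
    "ID": "feature_id",
    "Name": "protein_id",
    "F median": "fg_median",
    "B median": "bg_median",
    "B SD": "bg_sd",
    "Flags": "flag",
}

DEFAULT_CONTROL_REGEX = r"^CTRL"

#: normalized values at or below zero are floored to this before log2
LOG_FLOOR = 1e-6


@dataclass
class ArraySpot:
    """One quantitated spot of a scanned array."""

    block_id: int
    row: int
    col: int
    x: float
    y: float
    feature_id: str
    protein_id: str
    is_control: bool
    fg_median: float
    bg_median: float
    bg_sd: float
    flag: int = 0

    def __post_init__(self) -> None:
        if self.fg_median < 0:
            raise ValidationError(f"fg_median must be >= 0, got {self.fg_median}")
        if self.bg_sd < 0:
            raise ValidationError(f"bg_sd must be >= 0, got {self.bg_sd}")


@dataclass
class ArrayScan:
    """An ordered collection of spots from one scan condition."""

    spots: list[ArraySpot]
    condition: str  # "bound" or "mock"
    channel_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(s.block_id, s.row, s.col) for s in self.spots]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate (block, row, col) grid positions in scan")

    def __len__(self) -> int:
        return len(self.spots)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(s) for s in self.spots])
        df.attrs["condition"] = self.condition
        df.attrs["channel_label"] = self.channel_label
        return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gpr(
    path,
    condition: str,
    control_regex: str | None = DEFAULT_CONTROL_REGEX,
    control_ids: set[str] | None = None,
) -> ArrayScan:
    """Read a GenePix-Results-dialect tab-delimited scan file.

    The file starts with an ATF-style header block (``ATF<TAB>1.0``, a
    record-count line, quoted ``"key=value"`` records), followed by a
    column-header row and the tab-delimited data section.

    Control spots are flagged either by ``control_regex`` matched against the
    Name column, or by explicit membership of ID in ``control_ids``.
    """
    with open(path, "rt") as fh:
        lines = fh.read().splitlines()

    metadata: dict = {}
    header_idx = None
    for i, line in enumerate(lines):
        fields = line.split("\t")
        if "Block" in fields:
            header_idx = i
            break
        m = re.match(r'^"?([^="]+)=([^"]*)"?$', line.strip())
        if m:
            metadata[m.group(1)] = m.group(2)
    if header_idx is None:
        raise FormatError("no column-header row containing 'Block' found")

    columns = [c.strip('"') for c in lines[header_idx].split("\t")]
    missing = [c for c in GPR_COLUMNS if c not in columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")

    data_text = "\n".join(lines[header_idx:])
    df = pd.read_csv(io.StringIO(data_text), sep="\t")
    df.columns = [c.strip('"') for c in df.columns]
    if df.empty:
        raise DegenerateDataError("empty data section in scan file")

    rx = re.compile(control_regex) if control_regex else None
    spots = []
    for rec in df.to_dict("records"):
        name = str(rec["Name"]).strip('"')
        fid = str(rec["ID"]).strip('"')
        is_control = bool(
            (rx is not None and rx.search(name))
            or (control_ids is not None and fid in control_ids)
        )
        spots.append(
            ArraySpot(
                block_id=int(rec["Block"]),
                row=int(rec["Row"]),
                col=int(rec["Column"]),
                x=float(rec["X"]),
                y=float(rec["Y"]),
                feature_id=fid,
                protein_id=name,
                is_control=is_control,
                fg_median=float(rec["F median"]),
                bg_median=float(rec["B median"]),
                bg_sd=float(rec["B SD"]),
                flag=int(rec["Flags"]),
            )
        )
    return ArrayScan(spots=spots, condition=condition, metadata=metadata)


def write_gpr(scan: ArrayScan, path) -> None:
    """Write a scan in the same dialect :func:`read_gpr` consumes."""
    header_records = {"Type": "GenePix Results 3", **scan.metadata}
    cols = list(GPR_COLUMNS)
    with open(path, "wt") as fh:
        fh.write("ATF\t1.0\n")
        fh.write(f"{len(header_records)}\t{len(cols)}\n")
        for k, v in header_records.items():
            fh.write(f'"{k}={v}"\n')
        fh.write("\t".join(cols) + "\n")
        for s in scan.spots:
            fh.write(
                f"{s.block_id}\t{s.row}\t{s.col}\t{s.x:g}\t{s.y:g}\t"
                f"{s.feature_id}\t{s.protein_id}\t{s.fg_median:g}\t"
                f"{s.bg_median:g}\t{s.bg_sd:g}\t{s.flag}\n"
            )


# ---------------------------------------------------------------------------
# Per-spot statistics
# ---------------------------------------------------------------------------

def snr(spot: ArraySpot, fallback_bg_sd: float | None = None) -> float:
    """Signal-to-noise of one spot: (fg_median - bg_median) / bg_sd.

    May be negative.  When ``bg_sd`` is zero, ``fallback_bg_sd`` (typically
    the scan-wide median background SD) is substituted.
    """
    sd = spot.bg_sd
    if sd == 0:
        if fallback_bg_sd is None or fallback_bg_sd <= 0:
            raise DegenerateDataError("bg_sd is 0 and no usable fallback available")
        warnings.warn("bg_sd == 0; substituting scan-wide median bg_sd")
        sd = fallback_bg_sd
    return (spot.fg_median - spot.bg_median) / sd


def snr_table(scan: ArrayScan) -> pd.DataFrame:
    """Spot table with an ``snr`` column; zero bg_sd spots get the scan-wide
    median bg_sd substituted (degenerate-scan error if that is also zero)."""
    df = scan.to_frame()
    fallback = float(df["bg_sd"].median())
    sd = df["bg_sd"].to_numpy(dtype=float).copy()
    if (sd == 0).any():
        if fallback <= 0:
            raise DegenerateDataError("scan-wide median bg_sd is 0")
        warnings.warn(f"{int((sd == 0).sum())} spot(s) with bg_sd == 0; using scan median")
        sd[sd == 0] = fallback
    df["snr"] = (df["fg_median"] - df["bg_median"]) / sd
    return df


def normalize_to_controls(
    scan: ArrayScan, control_median_override: float | None = None
) -> pd.DataFrame:
    """Divide every spot's S/N by the median S/N of non-flagged control spots.

    The control median is recorded in ``result.attrs['control_median']``.
    """
    df = snr_table(scan)
    if control_median_override is not None:
        ctrl_median = float(control_median_override)
    else:
        ctrl = df[df["is_control"] & (df["flag"] == 0)]
        if ctrl.empty:
            raise ValidationError(
                "no usable (non-flagged) control spots; pass an explicit "
                "control-median override"
            )
        ctrl_median = float(ctrl["snr"].median())
    if ctrl_median == 0:
        raise DegenerateDataError("control median S/N is 0")
    df["norm_snr"] = df["snr"] / ctrl_median
    df.attrs["control_median"] = ctrl_median
    df.attrs["condition"] = scan.condition
    return df


def summarize_duplicates(normalized: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Average non-flagged duplicate spots per feature.

    Returns (per-feature table, list of features dropped because every
    duplicate carried a nonzero quality flag).
    """
    good = normalized[normalized["flag"] == 0]
    dropped = sorted(set(normalized["feature_id"]) - set(good["feature_id"]))
    agg = good.groupby("feature_id", sort=False).agg(
        protein_id=("protein_id", "first"),
        block_id=("block_id", "first"),
        x=("x", "mean"),
        y=("y", "mean"),
        is_control=("is_control", "any"),
        norm_snr=("norm_snr", "mean"),
        n_spots=("norm_snr", "size"),
    ).reset_index()
    agg.attrs = dict(normalized.attrs)
    return agg, dropped


# ---------------------------------------------------------------------------
# Local regression
# ---------------------------------------------------------------------------

def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def loess2d(
    z: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    frac: float = 0.3,
    eval_x: np.ndarray | None = None,
    eval_y: np.ndarray | None = None,
) -> np.ndarray:
    """2-D local linear regression of z on (x, y).

    Tricube weights over the ``frac`` nearest training neighbours of each
    evaluation point, coordinates standardized before distance computation.
    Returns fitted values at the training points, or at (eval_x, eval_y)
    when given.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    pts = np.column_stack([x, y]).astype(float)
    scale = pts.std(axis=0)
    scale[scale == 0] = 1.0
    pts = pts / scale
    if eval_x is None:
        qpts = pts
    else:
        qpts = np.column_stack([eval_x, eval_y]).astype(float) / scale
    k = max(int(np.ceil(frac * n)), 4)
    k = min(k, n)
    tree = cKDTree(pts)
    dist, idx = tree.query(qpts, k=k)
    fitted = np.empty(len(qpts))
    for i in range(len(qpts)):
        nbr = idx[i]
        d = dist[i]
        dmax = d[-1]
        w = _tricube(d / dmax) if dmax > 0 else np.ones_like(d)
        X = np.column_stack([np.ones(nbr.size), pts[nbr, 0], pts[nbr, 1]])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z[nbr] * sw, rcond=None)
        fitted[i] = beta[0] + beta[1] * qpts[i, 0] + beta[2] * qpts[i, 1]
    return fitted


# ---------------------------------------------------------------------------
# M-values and hit calling
# ---------------------------------------------------------------------------

MIN_GROUP_POINTS = 8  # smallest print-tip group the 1-D loess will attempt


def compute_m_values(
    bound: ArrayScan,
    mock: ArrayScan,
    span_printtip: float = 0.75,
    span_spatial: float = 0.3,
    log_floor: float = LOG_FLOOR,
    control_median_override: float | None = None,
) -> pd.DataFrame:
    """Per-feature twice-normalized magnitude change (M) with its A covariate.

    Raw difference D = log2(bound) - log2(mock) on duplicate-summarized,
    control-normalized S/N; stage 1 detrends D against A within each
    print-tip group; stage 2 detrends the residuals against (x, y) over the
    whole slide.  The stage-2 residual is the M-value.
    """
    tables = {}
    for scan in (bound, mock):
        norm = normalize_to_controls(scan, control_median_override)
        summ, dropped = summarize_duplicates(norm)
        if dropped:
            warnings.warn(f"{scan.condition}: {len(dropped)} feature(s) fully flagged, dropped")
        tables[scan.condition] = summ

    merged = tables["bound"].merge(
        tables["mock"][["feature_id", "norm_snr"]],
        on="feature_id",
        suffixes=("_bound", "_mock"),
        validate="1:1",
    )
    if merged.empty:
        raise DegenerateDataError("no features shared between bound and mock scans")

    vb = np.maximum(merged["norm_snr_bound"].to_numpy(dtype=float), log_floor)
    vm = np.maximum(merged["norm_snr_mock"].to_numpy(dtype=float), log_floor)
    lb, lm = np.log2(vb), np.log2(vm)
    d = lb - lm
    a = 0.5 * (lb + lm)

    # Trends are estimated on non-control features only (controls are the
    # normalization reference, their D sits at 0 by construction) and then
    # evaluated for every spot.
    feat = ~merged["is_control"].to_numpy()

    # stage 1: per print-tip group, robust M-vs-A loess
    resid1 = d.copy()
    blocks = merged["block_id"].to_numpy()
    for blk in np.unique(blocks):
        sel = blocks == blk
        train = sel & feat
        if train.sum() < MIN_GROUP_POINTS:
            warnings.warn(f"print-tip group {blk}: too few points for loess, skipped")
            continue
        fit = _sm_lowess(d[train], a[train], frac=span_printtip, it=3,
                         xvals=a[sel])
        resid1[sel] = d[sel] - fit

    # stage 2: whole-slide spatial loess on (x, y)
    x_all = merged["x"].to_numpy()
    y_all = merged["y"].to_numpy()
    fit2 = loess2d(resid1[feat], x_all[feat], y_all[feat], frac=span_spatial,
                   eval_x=x_all, eval_y=y_all)
    m = resid1 - fit2

    out = pd.DataFrame(
        {
            "feature_id": merged["feature_id"],
            "protein_id": merged["protein_id"],
            "is_control": merged["is_control"],
            "a_value": a,
            "m_value": m,
        }
    )
    out.attrs["span_printtip"] = span_printtip
    out.attrs["span_spatial"] = span_spatial
    return out


ISOFORM_DELIMITER = r"[.\-]"  # PROT12.2 / PROT12-2 -> PROT12


@dataclass
class HitCalls:
    """Result of thresholding an M-value table."""

    table: pd.DataFrame  # protein_id, a_value, m_value, is_hit (sorted desc by M)
    threshold: float
    mean: float
    sd: float
    unique_candidates: list[str]


def call_hits(
    m_table: pd.DataFrame,
    k: float = 1.0,
    isoform_delimiter: str = ISOFORM_DELIMITER,
) -> HitCalls:
    """Call receptor candidates at mean + k * SD of the M-value population.

    Control features are excluded from the population statistics and from the
    candidate list; values exactly at the threshold count as hits.  Isoforms
    are collapsed (protein_id prefix before the first delimiter) for the
    unique-candidate count.
    """
    if len(m_table) < 2:
        raise ValidationError("need at least 2 M-value records to call hits")
    pop = m_table.loc[~m_table["is_control"], "m_value"].to_numpy(dtype=float)
    mu = float(np.mean(pop))
    sd = float(np.std(pop, ddof=1))
    if sd == 0:
        warnings.warn("zero variance in M-value population; no hits called")
        threshold = np.inf
    else:
        threshold = mu + k * sd

    out = m_table.copy()
    out["is_hit"] = (~out["is_control"]) & (out["m_value"] >= threshold)
    out = out.sort_values("m_value", ascending=False).reset_index(drop=True)

    rx = re.compile(isoform_delimiter)
    uniq: list[str] = []
    seen: set[str] = set()
    for pid in out.loc[out["is_hit"], "protein_id"]:
        base = rx.split(str(pid), maxsplit=1)[0]
        if base not in seen:
            seen.add(base)
            uniq.append(base)
    return HitCalls(table=out, threshold=threshold, mean=mu, sd=sd, unique_candidates=uniq)
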