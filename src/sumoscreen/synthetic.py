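"""Seeded generators for every pipeline stage.

Each generator is a pure function of its config (same seed => identical
output, byte-identical after writing) and returns a machine-readable truth
object alongside the data, so the whole pipeline is testable offline.

Noise conventions: log-normal spot intensities for arrays, multiplicative
Gaussian noise for peak areas and binding responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import footprint as fp
from .arrays import ArrayScan, ArraySpot
from .binding import BindingCurve, bound_fraction
from .errors import ValidationError
from .motif import MotifPattern
from .nmr import TitrationSeries

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Arrays
# ---------------------------------------------------------------------------

@dataclass
class ArrayConfig:
    seed: int
    n_features: int = 2000
    duplicate_multiplicity: int = 2
    n_blocks: int = 16
    n_controls: int = 32
    n_spikes: int = 0
    spike_effect: float = 0.0  # log2 effect added in the bound channel
    printtip_sd: float = 0.3  # SD of per-block additive log2 offsets
    spatial_gradient: tuple[float, float] = (0.5, 0.5)  # log2 across the slide
    noise_sd: float = 0.15  # per-spot per-channel log2 noise
    base_log2: float = 6.0
    feature_sd: float = 1.5
    bg_mean: float = 100.0
    bg_sd_spot: float = 10.0  # constant local-background SD reported per spot
    spot_pitch: float = 200.0  # scanner units between spot centres


def gen_array(cfg: ArrayConfig) -> tuple[ArrayScan, ArrayScan, pd.DataFrame]:
    """Paired (bound, mock) scans with print-tip and spatial bias plus spikes.

    Duplicate spots of one feature sit in adjacent columns of the same block;
    spiked features carry ``spike_effect`` (log2) in the bound channel only.
    Truth table columns: feature_id, is_spike, effect.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_features + cfg.n_controls
    if cfg.n_spikes > cfg.n_features:
        raise ValidationError("more spikes than features")
    if cfg.n_spikes and cfg.spike_effect == 0:
        import warnings

        warnings.warn("spikes configured with zero effect")

    feature_ids = [f"FEAT{i:05d}" for i in range(cfg.n_features)]
    control_ids = [f"CTRL{i:03d}" for i in range(cfg.n_controls)]
    all_ids = feature_ids + control_ids
    spike_idx = rng.choice(cfg.n_features, size=cfg.n_spikes, replace=False)
    spike_set = {feature_ids[i] for i in sorted(spike_idx)}

    order = rng.permutation(n_total)

    # grid geometry: square-ish arrangement of blocks, duplicates side by side
    nbx = int(np.ceil(np.sqrt(cfg.n_blocks)))
    per_block = int(np.ceil(n_total / cfg.n_blocks))
    ncol_feat = int(np.ceil(np.sqrt(per_block)))
    ncol = ncol_feat * cfg.duplicate_multiplicity
    nrow = int(np.ceil(per_block / ncol_feat))
    block_w = (ncol + 2) * cfg.spot_pitch
    block_h = (nrow + 2) * cfg.spot_pitch
    slide_w = nbx * block_w
    slide_h = int(np.ceil(cfg.n_blocks / nbx)) * block_h

    mu_feature = cfg.base_log2 + rng.normal(0.0, cfg.feature_sd, size=n_total)
    block_offsets = rng.normal(0.0, cfg.printtip_sd, size=cfg.n_blocks)
    gx, gy = cfg.spatial_gradient

    spots_per_channel: dict[str, list[ArraySpot]] = {"bound": [], "mock": []}
    truth_rows = []
    for slot, fi in enumerate(order):
        fid = all_ids[fi]
        is_control = fi >= cfg.n_features
        block = slot // per_block
        within = slot % per_block
        r = within // ncol_feat
        c_feat = within % ncol_feat
        bx, by = block % nbx, block // nbx
        mu = mu_feature[fi]
        if is_control:
            mu = cfg.base_log2 + 2.0  # bright, condition-independent reference
        effect = cfg.spike_effect if fid in spike_set else 0.0
        for dup in range(cfg.duplicate_multiplicity):
            col = c_feat * cfg.duplicate_multiplicity + dup
            x = bx * block_w + (col + 1) * cfg.spot_pitch
            y = by * block_h + (r + 1) * cfg.spot_pitch
            bias = (
                block_offsets[block]
                + gx * (x / slide_w)
                + gy * (y / slide_h)
            )
            for condition in ("bound", "mock"):
                ell = mu + bias + rng.normal(0.0, cfg.noise_sd)
                if condition == "bound" and not is_control:
                    ell += effect
                bg = cfg.bg_mean * np.exp(rng.normal(0.0, 0.2))
                spots_per_channel[condition].append(
                    ArraySpot(
                        block_id=block + 1,
                        row=r + 1,
                        col=col + 1,
                        x=round(x, 1),
                        y=round(y, 1),
                        feature_id=fid,
                        protein_id=fid if is_control else f"PROT{fi:05d}",
                        is_control=is_control,
                        fg_median=round(bg + 2.0**ell, 2),
                        bg_median=round(bg, 2),
                        bg_sd=cfg.bg_sd_spot,
                        flag=0,
                    )
                )
        if not is_control:
            truth_rows.append(
                {"feature_id": fid, "is_spike": fid in spike_set, "effect": effect}
            )

    bound = ArrayScan(spots_per_channel["bound"], condition="bound",
                      metadata={"Seed": str(cfg.seed)})
    mock = ArrayScan(spots_per_channel["mock"], condition="mock",
                     metadata={"Seed": str(cfg.seed)})
    truth = pd.DataFrame(truth_rows).sort_values("feature_id").reset_index(drop=True)
    return bound, mock, truth


# ---------------------------------------------------------------------------
# Footprinting
# ---------------------------------------------------------------------------

@dataclass
class FootprintConfig:
    seed: int
    sequence: str | None = None  # random 164-mer when omitted
    sequence_length: int = 164
    masked_spans: list = field(default_factory=list)  # [(start, end, effect<0)]
    unmasked_spans: list = field(default_factory=list)  # [(start, end, effect>0)]
    baseline_p: tuple[float, float] = (0.2, 0.6)  # uniform range per peptide
    noise_sd: float = 0.02  # additive SD on per-replicate P
    replicates: int = 3
    max_missed: int = 0
    total_area: float = 1e6


def gen_footprint(cfg: FootprintConfig) -> tuple[list[fp.FootprintRecord], dict]:
    """Triplicate labelled/unlabelled area pairs with planted span effects.

    Truth: the sequence, planted spans, and the spans of peptides overlapping
    a planted span (the expected masked/unmasked call sets).
    """
    rng = np.random.default_rng(cfg.seed)
    seq = cfg.sequence or "".join(
        rng.choice(list(AA_ALPHABET), size=cfg.sequence_length)
    )
    peptides = fp.digest(seq, max_missed=cfg.max_missed)
    spans = [(s, e, eff) for s, e, eff in cfg.masked_spans + cfg.unmasked_spans]
    for s, e, _ in spans:
        if s < 1 or e > len(seq):
            raise ValidationError(f"planted span {s}-{e} outside sequence")

    records = []
    truth_masked, truth_unmasked = set(), set()
    for pep in peptides:
        p0 = rng.uniform(*cfg.baseline_p)
        effect = 0.0
        for s, e, eff in spans:
            if pep.start <= e and pep.end >= s:  # overlap
                if abs(eff) > abs(effect):
                    effect = eff
        if effect < 0:
            truth_masked.add((pep.start, pep.end))
        elif effect > 0:
            truth_unmasked.add((pep.start, pep.end))
        for condition, mean_p in (("apo", p0), ("bound", p0 + effect)):
            for rep in range(1, cfg.replicates + 1):
                p = float(np.clip(mean_p + rng.normal(0.0, cfg.noise_sd), 1e-3, 1 - 1e-3))
                total = cfg.total_area * np.exp(rng.normal(0.0, 0.1))
                records.append(
                    fp.FootprintRecord(
                        peptide=pep, condition=condition, replicate=rep,
                        area_labelled=p * total, area_unlabelled=(1 - p) * total,
                    )
                )
    truth = {
        "sequence": seq,
        "planted_spans": spans,
        "masked_peptides": truth_masked,
        "unmasked_peptides": truth_unmasked,
    }
    return records, truth


# ---------------------------------------------------------------------------
# NMR titrations
# ---------------------------------------------------------------------------

@dataclass
class NmrConfig:
    seed: int
    n_residues: int = 80
    site_residues: tuple = (40, 41, 42, 43, 44, 45)
    equivalents: tuple = (0.0, 0.1, 0.5, 1.0, 4.0)
    apparent_k: float = 0.05  # equivalents at half-occupancy
    depth: float = 0.95  # fraction of intensity lost at saturation
    noise_sd: float = 0.02  # fractional intensity noise
    i0: float = 100.0
    proline_fraction: float = 0.05


def gen_nmr_titration(cfg: NmrConfig) -> tuple[list[TitrationSeries], set[int]]:
    """Planted-binding-site titration: site residues broaden with occupancy
    theta(e) = e / (e + apparent_k); off-site residues fluctuate with noise.
    Prolines are emitted unassigned.  Truth is the planted site residue set."""
    rng = np.random.default_rng(cfg.seed)
    site = set(cfg.site_residues)
    if any(r < 1 or r > cfg.n_residues for r in site):
        raise ValidationError("site residues outside 1..n_residues")
    series = []
    for res in range(1, cfg.n_residues + 1):
        if res in site:
            aa = rng.choice([c for c in AA_ALPHABET if c != "P"])
        else:
            aa = rng.choice(list(AA_ALPHABET)) if rng.random() > cfg.proline_fraction else "P"
        intensities = []
        for e in cfg.equivalents:
            theta = e / (e + cfg.apparent_k) if res in site else 0.0
            i = cfg.i0 * (1.0 - cfg.depth * theta)
            if cfg.noise_sd > 0 and e > 0:
                i *= 1.0 + rng.normal(0.0, cfg.noise_sd)
            intensities.append(float(max(i, 0.0)))
        series.append(
            TitrationSeries(
                residue=res, aa=str(aa),
                equivalents=list(cfg.equivalents),
                intensities=intensities,
                assigned=(aa != "P"),
            )
        )
    return series, site


# ---------------------------------------------------------------------------
# Proteomes
# ---------------------------------------------------------------------------

@dataclass
class ProteomeConfig:
    seed: int
    n_proteins: int = 50
    length_range: tuple[int, int] = (150, 400)
    n_motif_proteins: int = 12
    pattern: str = "K[SDE][VLI][DES][FVLI]"
    n_receptors: int = 10
    receptor_motif_overlap: int = 7  # receptors drawn from motif-positive set


def gen_proteome(cfg: ProteomeConfig) -> tuple[list[tuple[str, str]], dict]:
    """Random proteome with motifs spliced at known positions.

    Returns FASTA records as (id, sequence) pairs and a truth dict with the
    planted hits, the receptor set (built with a configured overlap with
    motif-positive proteins) and the universe."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_motif_proteins > cfg.n_proteins:
        raise ValidationError("more motif proteins than proteins")
    pattern = MotifPattern.from_string(cfg.pattern)
    ids = [f"SP{i:04d}" for i in range(cfg.n_proteins)]
    motif_proteins = set(rng.choice(cfg.n_proteins, cfg.n_motif_proteins, replace=False))

    records, planted = [], []
    for i, pid in enumerate(ids):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = list(rng.choice(list(AA_ALPHABET), size=length))
        if i in motif_proteins:
            motif = "".join(str(rng.choice(sorted(pos))) for pos in pattern.positions)
            start = int(rng.integers(1, length - len(motif) + 1))
            seq[start - 1 : start - 1 + len(motif)] = list(motif)
            planted.append({"protein_id": pid, "start": start, "matched": motif})
        records.append((pid, "".join(seq)))

    motif_ids = [ids[i] for i in sorted(motif_proteins)]
    other_ids = [p for p in ids if p not in set(motif_ids)]
    n_from_motif = min(cfg.receptor_motif_overlap, len(motif_ids), cfg.n_receptors)
    receptors = set(rng.choice(motif_ids, n_from_motif, replace=False))
    n_rest = cfg.n_receptors - n_from_motif
    if n_rest > 0:
        receptors |= set(rng.choice(other_ids, n_rest, replace=False))

    truth = {
        "planted_hits": planted,
        "receptor_ids": receptors,
        "universe_ids": set(ids),
    }
    return records, truth


# ---------------------------------------------------------------------------
# Binding curves
# ---------------------------------------------------------------------------

@dataclass
class BindingConfig:
    seed: int
    true_kd: float = 3.2  # nM
    bmax: float = 1.0
    offset: float = 0.0
    target_conc: float = 5.0  # nM fixed labelled partner
    top_conc: float = 500.0  # nM, highest of the dilution series
    n_dilutions: int = 16
    replicates: int = 3
    noise_frac: float = 0.02  # multiplicative Gaussian response noise


def gen_binding_curve(cfg: BindingConfig) -> tuple[list[BindingCurve], dict]:
    """Doubling-dilution titrations from the depletion isotherm at the
    configured true parameters, with multiplicative response noise."""
    rng = np.random.default_rng(cfg.seed)
    conc = cfg.top_conc / 2.0 ** np.arange(cfg.n_dilutions)
    curves = []
    for rep in range(cfg.replicates):
        f = bound_fraction(cfg.target_conc, conc, cfg.true_kd)
        resp = cfg.offset + cfg.bmax * f
        if cfg.noise_frac > 0:
            resp = resp * (1.0 + rng.normal(0.0, cfg.noise_frac, size=conc.size))
        curves.append(
            BindingCurve(conc.copy(), resp, target_conc=cfg.target_conc, replicate=rep)
        )
    truth = {"kd": cfg.true_kd, "bmax": cfg.bmax, "offset": cfg.offset,
             "target_conc": cfg.target_conc}
    return curves, truth


# ---------------------------------------------------------------------------
# File emission (CLI `simulate` backend)
# ---------------------------------------------------------------------------

def write_fasta(records: list[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def footprint_records_to_frame(records: list[fp.FootprintRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide_start": [r.peptide.start for r in records],
            "peptide_end": [r.peptide.end for r in records],
            "condition": [r.condition for r in records],
            "replicate": [r.replicate for r in records],
            "area_labelled": [r.area_labelled for r in records],
            "area_unlabelled": [r.area_unlabelled for r in records],
        }
    )


def nmr_series_to_frame(series: list[TitrationSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for e, i in zip(s.equivalents, s.intensities):
            rows.append(
                {"residue": s.residue, "aa": s.aa, "equivalents": e,
                 "intensity": i, "assigned": int(s.assigned)}
            )
    return pd.DataFrame(rows)


def binding_curves_to_frame(curves: list[BindingCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for conc, resp in zip(c.concentrations, c.responses):
            rows.append(
                {"concentration_nM": conc, "response": resp, "replicate": c.replicate}
            )
    return pd.DataFrame(rows)


def dump_truth(truth, path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "wt") as fh:
        json.dump(truth, fh, indent=1, default=default, sort_keys=True)


def config_from_mapping(cls, mapping: dict):
    """Build a stage config from a loosely typed key-value mapping."""
    fields = {f: t for f, t in cls.__dataclass_fields__.items()}
    kwargs = {}
    for key, value in mapping.items():
        if key not in fields:
            raise ValidationError(f"unknown {cls.__name__} key '{key}'")
        kwargs[key] = value
    return cls(**kwargs)
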