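"""Covalent-labelling (carbene) footprinting quantitation.

Fractional modification per tryptic peptide, masked/unmasked classification
between apo and partner-bound conditions, and painting of peptide classes
onto the residues of the target sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class PeptideClass(str, Enum):
    MASKED = "masked"
    UNMASKED = "unmasked"
    UNCHANGED = "unchanged"
    UNDETECTED = "undetected"


#: residue-class colours for structure painting (hex RGB)
CLASS_COLOURS = {
    PeptideClass.MASKED: "#FF0000",
    PeptideClass.UNMASKED: "#FFFF00",
    PeptideClass.UNCHANGED: "#0000FF",
    PeptideClass.UNDETECTED: "#ADD8E6",
}


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with its 1-based inclusive span in the parent."""

    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"end {self.end} < start {self.start}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError("sequence length does not match span")


@dataclass
class FootprintRecord:
    """Labelled/unlabelled peak areas for one peptide, replicate, condition."""

    peptide: Peptide
    condition: str  # "apo" or "bound"
    replicate: int
    area_labelled: float
    area_unlabelled: float

    def __post_init__(self) -> None:
        if self.area_labelled < 0 or self.area_unlabelled < 0:
            raise ValidationError("peak areas must be >= 0")
        if self.area_labelled == 0 and self.area_unlabelled == 0:
            raise ValidationError("labelled and unlabelled areas both zero")


@dataclass
class FootprintResult:
    peptide: Peptide
    p_apo_mean: float
    p_bound_mean: float
    p_apo_sd: float
    p_bound_sd: float
    t_pvalue: float
    effect: float  # p_bound_mean - p_apo_mean
    klass: PeptideClass
    reason: str = ""


def digest(sequence: str, max_missed: int = 1) -> list[Peptide]:
    """In-silico trypsin digest: cut after K or R unless the next residue is P.

    Returns fully cleaved peptides plus all peptides with up to ``max_missed``
    missed cleavages, 1-based inclusive spans.
    """
    bad = [i + 1 for i, c in enumerate(sequence) if c not in STANDARD_AA]
    if bad:
        raise ValidationError(f"non-standard residue letter(s) at position(s) {bad}")

    cut_after = [
        i
        for i, c in enumerate(sequence)
        if c in "KR" and (i + 1 >= len(sequence) or sequence[i + 1] != "P")
    ]
    bounds = [0] + [i + 1 for i in cut_after]
    if bounds[-1] != len(sequence):
        bounds.append(len(sequence))

    peptides = []
    nseg = len(bounds) - 1
    for i in range(nseg):
        for missed in range(0, max_missed + 1):
            j = i + missed + 1
            if j > nseg:
                break
            s, e = bounds[i], bounds[j]
            peptides.append(
                Peptide(start=s + 1, end=e, sequence=sequence[s:e], missed_cleavages=missed)
            )
    return peptides


def fractional_modification(area_labelled: float, area_unlabelled: float) -> float:
    """P = A(labelled) / (A(labelled) + A(unlabelled)), in [0, 1]."""
    total = area_labelled + area_unlabelled
    if total <= 0:
        raise ValidationError("labelled + unlabelled area must be > 0")
    return area_labelled / total


def _welch(apo: np.ndarray, bound: np.ndarray) -> float:
    """Two-sided Welch t-test p-value, degenerate zero-variance cases handled."""
    if np.std(apo, ddof=1) == 0 and np.std(bound, ddof=1) == 0:
        return 1.0 if np.mean(apo) == np.mean(bound) else 0.0
    return float(stats.ttest_ind(apo, bound, equal_var=False).pvalue)


def classify_peptides(
    records: list[FootprintRecord], alpha: float = 0.05, fdr: bool = False
) -> list[FootprintResult]:
    """Per-peptide masking/unmasking classification.

    Per-replicate fractional modifications are compared between conditions
    with a two-sided Welch t-test; a peptide is *masked* when bound < apo at
    p < alpha, *unmasked* when bound > apo at p < alpha.  With ``fdr=True``
    Benjamini-Hochberg adjusted p-values are used against the same alpha.
    """
    by_pep: dict[Peptide, dict[str, list[float]]] = {}
    for rec in records:
        p = fractional_modification(rec.area_labelled, rec.area_unlabelled)
        by_pep.setdefault(rec.peptide, {"apo": [], "bound": []})[rec.condition].append(p)

    results = []
    for pep, groups in by_pep.items():
        apo = np.asarray(groups["apo"], dtype=float)
        bound = np.asarray(groups["bound"], dtype=float)
        if len(apo) < 2 or len(bound) < 2:
            results.append(
                FootprintResult(
                    peptide=pep,
                    p_apo_mean=float(np.mean(apo)) if len(apo) else np.nan,
                    p_bound_mean=float(np.mean(bound)) if len(bound) else np.nan,
                    p_apo_sd=np.nan,
                    p_bound_sd=np.nan,
                    t_pvalue=np.nan,
                    effect=np.nan,
                    klass=PeptideClass.UNDETECTED,
                    reason="fewer than 2 replicates in a condition",
                )
            )
            continue
        effect = float(np.mean(bound) - np.mean(apo))
        pval = _welch(apo, bound)
        results.append(
            FootprintResult(
                peptide=pep,
                p_apo_mean=float(np.mean(apo)),
                p_bound_mean=float(np.mean(bound)),
                p_apo_sd=float(np.std(apo, ddof=1)),
                p_bound_sd=float(np.std(bound, ddof=1)),
                t_pvalue=pval,
                effect=effect,
                klass=PeptideClass.UNCHANGED,  # set below
            )
        )

    tested = [r for r in results if np.isfinite(r.t_pvalue)]
    if fdr and tested:
        order = np.argsort([r.t_pvalue for r in tested])
        n = len(tested)
        adj = np.empty(n)
        prev = 1.0
        for rank, i in enumerate(reversed(order)):
            q = tested[i].t_pvalue * n / (n - rank)
            prev = min(prev, q)
            adj[i] = prev
        effective = {id(tested[i]): adj[i] for i in range(n)}
    else:
        effective = {id(r): r.t_pvalue for r in tested}

    for r in tested:
        if effective[id(r)] < alpha and r.effect < 0:
            r.klass = PeptideClass.MASKED
        elif effective[id(r)] < alpha and r.effect > 0:
            r.klass = PeptideClass.UNMASKED
        else:
            r.klass = PeptideClass.UNCHANGED
    return results


#: conflict precedence when peptides overlap (higher wins at equal |effect|)
_CLASS_PRIORITY = {
    PeptideClass.UNDETECTED: 0,
    PeptideClass.UNCHANGED: 1,
    PeptideClass.MASKED: 2,
    PeptideClass.UNMASKED: 2,
}


def map_to_residues(results: list[FootprintResult], length: int) -> list[PeptideClass]:
    """Paint peptide classes onto residues 1..length.

    Residues covered by conflicting peptides take the class of the peptide
    with the larger |effect| among significant ones; unchanged beats
    undetected; uncovered residues stay undetected.
    """
    klass = [PeptideClass.UNDETECTED] * length
    strength = [(-1, -1.0)] * length  # (priority, |effect|)
    for res in results:
        pep = res.peptide
        if pep.start < 1 or pep.end > length:
            raise ValidationError(f"peptide span {pep.start}-{pep.end} outside 1-{length}")
        prio = _CLASS_PRIORITY[res.klass]
        eff = abs(res.effect) if np.isfinite(res.effect) else 0.0
        key = (prio, eff if prio == 2 else 0.0)
        for i in range(pep.start - 1, pep.end):
            if key > strength[i]:
                strength[i] = key
                klass[i] = res.klass
    return klass


def results_to_frame(results: list[FootprintResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "peptide_start": r.peptide.start,
                "peptide_end": r.peptide.end,
                "peptide_sequence": r.peptide.sequence,
                "p_apo_mean": r.p_apo_mean,
                "p_bound_mean": r.p_bound_mean,
                "p_apo_sd": r.p_apo_sd,
                "p_bound_sd": r.p_bound_sd,
                "effect": r.effect,
                "t_pvalue": r.t_pvalue,
                "class": r.klass.value,
            }
        )
    return pd.DataFrame(rows)


def write_attribute_script(residue_map, path, chain_id: str = "A", colours=None) -> None:
    """Emit a per-residue attribute text file for molecular viewers.

    One line per residue: ``<chain>:<resnum><TAB><label><TAB><hex colour>``.
    ``residue_map`` entries may be :class:`PeptideClass` values or arbitrary
    string labels (colour then looked up in ``colours``).
    """
    colours = colours or {k.value: v for k, v in CLASS_COLOURS.items()}
    with open(path, "wt") as fh:
        fh.write("# residue attribute map\n")
        fh.write(f"# chain {chain_id}\n")
        fh.write("# resnum\tlabel\tcolour\n")
        for i, klass in enumerate(residue_map, start=1):
            label = klass.value if isinstance(klass, PeptideClass) else str(klass)
            fh.write(f"{chain_id}:{i}\t{label}\t{colours.get(label, '#808080')}\n")


def read_attribute_script(path) -> list[str]:
    """Parse a file written by :func:`write_attribute_script` back to labels."""
    labels = []
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _, label, _ = line.rstrip("\n").split("\t")
            labels.append(label)
    return labels
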