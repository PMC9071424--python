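"""Short-linear-motif proteome scanning and receptor enrichment.

Scans FASTA proteomes for the XRCC4-like SIM pattern (default
K-[SDE]-[VLI]-[DES]-[FVLI]), annotates the acidic context of each hit and
tests over-representation of a receptor set among motif-positive proteins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import SeqIO
from scipy import stats

from .errors import FormatError, ValidationError

AMBIGUOUS = set("XBZJUO*")  # never match any position set

DEFAULT_PATTERN = "K[SDE][VLI][DES][FVLI]"


@dataclass(frozen=True)
class MotifPattern:
    """Ordered allowed-residue sets, one per motif position."""

    positions: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if not self.positions or any(not p for p in self.positions):
            raise ValidationError("pattern needs >= 1 non-empty position set")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_string(cls, text: str = DEFAULT_PATTERN) -> "MotifPattern":
        """Parse bracket notation like ``K[SDE][VLI][DES][FVLI]``."""
        if not re.fullmatch(r"(?:\[[A-Za-z]+\]|[A-Za-z])+", text or ""):
            raise ValidationError(f"cannot parse pattern '{text}'")
        positions = [
            frozenset((tok[0] or tok[1]).upper())
            for tok in re.findall(r"\[([A-Za-z]+)\]|([A-Za-z])", text)
        ]
        return cls(tuple(positions))

    def matches(self, window: str) -> bool:
        if len(window) != len(self.positions):
            return False
        for ch, allowed in zip(window.upper(), self.positions):
            if ch in AMBIGUOUS or ch not in allowed:
                return False
        return True


@dataclass
class MotifHit:
    protein_id: str
    start: int  # 1-based position of the first motif residue
    matched: str
    acidic_context: bool = False
    acidic_count: int = 0


def scan_sequence(protein_id: str, sequence: str, pattern: MotifPattern) -> list[MotifHit]:
    """All (overlapping) pattern matches in one sequence, 1-based starts."""
    w = len(pattern)
    seq = sequence.upper()
    return [
        MotifHit(protein_id=protein_id, start=i + 1, matched=seq[i : i + w])
        for i in range(len(seq) - w + 1)
        if pattern.matches(seq[i : i + w])
    ]


def scan(fasta_path, pattern: MotifPattern | None = None) -> list[MotifHit]:
    """Scan every record of a FASTA proteome; deterministic file order."""
    pattern = pattern or MotifPattern.from_string()
    hits = []
    try:
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
    except Exception as exc:  # Bio raises assorted ValueErrors on bad input
        raise FormatError(f"unreadable FASTA: {exc}") from exc
    for rec in records:
        hits.extend(scan_sequence(rec.id, str(rec.seq), pattern))
    return hits


def acidic_context(
    hit: MotifHit, sequence: str, window: int = 5, min_count: int = 2
) -> MotifHit:
    """Annotate a hit with the D/E count in the flanking windows.

    ``window`` residues each side of the motif (clipped at the termini);
    context is true when the count reaches ``min_count``.
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    seq = sequence.upper()
    i0 = hit.start - 1
    left = seq[max(0, i0 - window) : i0]
    right = seq[i0 + len(hit.matched) : i0 + len(hit.matched) + window]
    count = sum(c in "DE" for c in left + right)
    hit.acidic_count = count
    hit.acidic_context = count >= min_count
    return hit


@dataclass
class EnrichmentResult:
    k: int  # motif-positive receptors
    K: int  # receptors in universe
    n: int  # motif-positive proteins
    N: int  # universe size
    odds_ratio: float
    p_value: float


def enrichment(
    hits: list[MotifHit], receptor_ids: set[str], universe_ids: set[str]
) -> EnrichmentResult:
    """One-sided Fisher exact test (hypergeometric upper tail) for receptor
    over-representation among motif-positive proteins.

    Presence/absence per protein feeds the 2x2 table, not hit counts.  The
    odds ratio uses a Haldane 0.5 correction when any cell is zero.
    """
    if not universe_ids:
        raise ValidationError("empty universe")
    if not receptor_ids <= universe_ids:
        raise ValidationError("receptor_ids must be a subset of universe_ids")
    motif_pos = {h.protein_id for h in hits} & universe_ids
    N = len(universe_ids)
    K = len(receptor_ids)
    n = len(motif_pos)
    k = len(motif_pos & receptor_ids)

    # upper tail P(X >= k), X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))

    a, b = k, K - k
    c, d = n - k, (N - K) - (n - k)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return EnrichmentResult(k=k, K=K, n=n, N=N, odds_ratio=float(odds), p_value=p)


def read_id_list(path) -> set[str]:
    """One identifier per line; blank lines and #-comments ignored."""
    out = set()
    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
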