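"""AU-rich element (ARE) calling and candidate-gene classification.

AREs are cis-regulatory elements in 3'UTRs that destabilise transcripts.
Three classes are recognised in the literature:

* Class I  — clustered AUUUA pentamers, each sitting in a U-rich context;
* Class II — at least two overlapping/chained ``UUAUUUA(U/A)(U/A)`` core
  motifs inside a U-rich region (the classic overlapping-pentamer ARE of
  early-response cytokines);
* Class III — a generally AU/U-rich stretch with no canonical pentamer.

The numeric ARE score implemented here is a simple, fully documented local
scheme (pentamer count plus context and clustering bonuses); it is *not* the
scoring function of any external web service, which this package does not
query.  The binary ARE+/ARE- call combines a curated database-membership
flag supplied as input metadata with the local score and a strict ``> 3``
threshold.

Candidate filtering follows the screening rules used for the wound-age
panel: differential expression at |log2FC| > 1 and adjusted P < 0.05 (both
strict), and exclusion of genes annotated to more than one GO top-level
category so that each candidate belongs to exactly one of CC/BP/MF.
Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PENTAMER = "AUUUA"
CLASS_II_CORE = re.compile(r"(?=(UUAUUUA[UA][UA]))")

#: fraction of U required in the 20-nt window centred on a pentamer
U_RICH_FRACTION = 0.60
U_RICH_WINDOW = 20
#: Class I: two context-positive pentamers must fit in a window this long
CLASS_I_SPAN = 50
#: Class II chaining: next core may start at most this far past the previous end
CLASS_II_GAP = 2
#: Class III window composition thresholds
CLASS_III_WINDOW = 30
CLASS_III_AU_FRACTION = 0.70
CLASS_III_U_FRACTION = 0.40

ARE_POS = "ARE+"
ARE_NEG = "ARE-"
GO_CATEGORIES = ("CC", "BP", "MF")
SUBGROUPS = ("ARE-CC", "ARE-BP", "ARE-MF", "ARE+CC", "ARE+BP", "ARE+MF")
EXCLUDED = "excluded"

DEFAULT_ARE_THRESHOLD = 3.0


@dataclass(frozen=True)
class AREHit:
    """One motif occurrence, 0-based half-open coordinates."""

    start: int
    end: int
    motif_kind: str  # "pentamer" or "classII_core"
    u_rich_context: bool


@dataclass
class GeneRecord:
    """One candidate mRNA with its screening annotations."""

    symbol: str
    accession: str = ""
    are_status: Optional[str] = None  # "ARE+" / "ARE-"
    are_class: str = "none"  # "I" / "II" / "III" / "none"
    are_score: float = 0.0
    in_ared: bool = False
    go_category: tuple[str, ...] = ()
    subgroup: Optional[str] = None
    log2fc: float = 0.0
    adj_p: float = 1.0
    efficiency: float = 1.0
    is_reference: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.go_category, str):
            self.go_category = (self.go_category,) if self.go_category else ()
        else:
            self.go_category = tuple(self.go_category)


def _validate_rna(seq: str) -> None:
    for i, base in enumerate(seq):
        if base not in "ACGU":
            raise ValueError(
                f"non-ACGU character {base!r} at position {i}; "
                "transliterate DNA with T->U before scanning"
            )


def transliterate(seq: str) -> str:
    """Uppercase and convert a DNA-alphabet sequence to RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def _u_fraction(seq: str, center: int, width: int = U_RICH_WINDOW) -> float:
    # positions beyond the sequence ends count as non-U, so context calls
    # are stable under embedding (keeps the score additive across spacers)
    half = width // 2
    lo = max(0, center - half)
    hi = min(len(seq), center + half)
    return seq[lo:hi].count("U") / width


def scan_pentamers(seq: str) -> list[AREHit]:
    """Find every AUUUA occurrence (overlaps included), in ascending order.

    A hit's ``u_rich_context`` is True when the 20-nt window centred on the
    pentamer is at least 60% U (the window is truncated at sequence ends).
    """
    _validate_rna(seq)
    hits: list[AREHit] = []
    for i in range(len(seq) - 4):
        if seq[i : i + 5] == PENTAMER:
            context = _u_fraction(seq, i + 2) >= U_RICH_FRACTION
            hits.append(AREHit(i, i + 5, "pentamer", context))
    return hits


def _class_ii_hits(seq: str) -> list[AREHit]:
    hits = []
    for m in CLASS_II_CORE.finditer(seq):
        start = m.start(1)
        end = start + 9
        context = _u_fraction(seq, start + 4) >= U_RICH_FRACTION
        hits.append(AREHit(start, end, "classII_core", context))
    return hits


def _has_class_ii(cores: Sequence[AREHit]) -> bool:
    """>= 2 chained context-positive cores (overlap or gap <= CLASS_II_GAP)."""
    chain = 0
    prev_end = None
    for h in cores:
        if not h.u_rich_context:
            chain = 0
            prev_end = None
            continue
        if prev_end is not None and h.start <= prev_end + CLASS_II_GAP:
            chain += 1
            if chain >= 2:
                return True
        else:
            chain = 1
        prev_end = max(prev_end, h.end) if prev_end is not None else h.end
    return False


def _has_class_i(pentamers: Sequence[AREHit]) -> bool:
    rich = [h for h in pentamers if h.u_rich_context]
    for a, b in zip(rich, rich[1:]):
        if b.end - a.start <= CLASS_I_SPAN:
            return True
    return False


def _has_class_iii(seq: str) -> bool:
    n = len(seq)
    width = min(CLASS_III_WINDOW, n)
    if width == 0:
        return False
    for lo in range(0, n - width + 1):
        window = seq[lo : lo + width]
        u = window.count("U")
        au = u + window.count("A")
        if au / width >= CLASS_III_AU_FRACTION and u / width >= CLASS_III_U_FRACTION:
            return True
    return False


def classify_are(seq: str) -> tuple[str, list[AREHit]]:
    """Assign an ARE class with precedence II > I > III > none.

    Returns the class label and all motif hits (pentamers, plus Class II
    cores when the sequence is Class II), sorted by start.
    """
    pentamers = scan_pentamers(seq)
    cores = _class_ii_hits(seq)
    if _has_class_ii(cores):
        hits = sorted(pentamers + cores, key=lambda h: (h.start, h.end))
        return "II", hits
    if _has_class_i(pentamers):
        return "I", pentamers
    if not pentamers and _has_class_iii(seq):
        return "III", []
    return "none", pentamers


def are_score(seq: str) -> float:
    """Local ARE score: pentamer count with context and clustering bonuses.

    1.0 per AUUUA pentamer, +0.5 for each pentamer in a U-rich context,
    +1.0 for each consecutive pentamer pair separated by <= 10 nt.  A
    motif-free sequence scores 0.  Additive under concatenation through a
    motif-free G/C spacer of >= 20 nt.
    """
    hits = scan_pentamers(seq)
    score = 0.0
    for h in hits:
        score += 1.0
        if h.u_rich_context:
            score += 0.5
    for a, b in zip(hits, hits[1:]):
        if b.start - a.end <= 10:
            score += 1.0
    return score


def call_are_status(
    record: GeneRecord,
    seq: Optional[str] = None,
    threshold: float = DEFAULT_ARE_THRESHOLD,
) -> str:
    """Binary ARE call: database membership gated by the local score.

    With a sequence, ARE+ requires both the curated-database flag and a
    score strictly greater than ``threshold``; without one, the database
    flag alone decides.
    """
    if seq is not None:
        return ARE_POS if (record.in_ared and are_score(seq) > threshold) else ARE_NEG
    return ARE_POS if record.in_ared else ARE_NEG


def filter_de_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Keep differentially expressed rows: |log2FC| > 1 and adj. P < 0.05.

    Both comparisons are strict, so boundary values (log2FC exactly +/-1,
    adjusted P exactly 0.05) are excluded.
    """
    fc = pd.to_numeric(table["log2fc"])
    p = pd.to_numeric(table["adj_p"])
    if not fc.map(lambda v: v == v and abs(v) != float("inf")).all():
        raise ValueError("log2fc must be finite")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("adj_p must lie in [0, 1]")
    keep = ((fc > 1) | (fc < -1)) & (p < 0.05)
    return table.loc[keep]


def assign_go_subgroup(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Cross ARE status with the GO category into the six subgroup labels.

    Genes annotated to zero or multiple GO categories are marked excluded;
    reference genes carry no subgroup.
    """
    out = []
    for rec in records:
        if rec.is_reference:
            out.append(replace(rec, subgroup=None))
            continue
        gos = rec.go_category
        if len(gos) != 1 or gos[0] not in GO_CATEGORIES:
            if len(gos) == 0:
                logger.warning("gene %s has no GO category; excluded", rec.symbol)
            out.append(replace(rec, subgroup=EXCLUDED))
            continue
        if rec.are_status not in (ARE_POS, ARE_NEG):
            raise ValueError(f"gene {rec.symbol} has no ARE status call")
        out.append(replace(rec, subgroup=f"{rec.are_status}{gos[0]}"))
    return out
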