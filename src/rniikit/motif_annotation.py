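"""Degenerate short-linear-motif scanning and per-sequence feature calls.

Three motif classes drive the feature table for RNase II-family proteins:

* the RNII active-site block ``DxxxxxDxDD``, whose 1st, 9th and 10th
  positions are the magnesium-coordinating aspartates (D201/D209/D210 in
  E. coli RNase II numbering) — a sequence has the *active-site signature*
  when all three are aspartate at the homologous alignment columns;
* the NDR/Cbk1 kinase phosphorylation consensus ``Hxxxx[ST]`` with at least
  one basic residue (K/R) among designated wildcard positions;
* the Cbk1 docking consensus ``[YF]x[FP]``.

A classical nuclear localisation signal (NLS) in a loop of CSD1 is called
not by motif but by counting basic residues in a configured reference
window.

Active-site calls are *alignment-positional*: the catalytic columns are
located by anchoring on a declared active homolog, because pseudonucleases
lack the motif entirely and cannot be found by de novo scanning.

The ambiguity character ``'X'`` never satisfies any motif position class,
wildcards included (conservative calling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import pandas as pd

from .family_io import (
    AA20,
    GAP,
    AlignedFamily,
    ColumnMap,
    DomainSpec,
    FamilyError,
    build_column_map,
)


class MotifError(ValueError):
    """Raised for malformed motif definitions or mis-anchored calls."""


@dataclass(frozen=True)
class SideCondition:
    """Require >= min_count of `residues` among given wildcard positions."""

    positions: tuple[int, ...]  # 1-based positions within the motif
    residues: frozenset[str]
    min_count: int = 1

    def satisfied(self, window: str) -> bool:
        n = sum(1 for p in self.positions if window[p - 1] in self.residues)
        return n >= self.min_count


@dataclass(frozen=True)
class MotifDefinition:
    """An ordered pattern of position classes with an optional side condition.

    Each position class is a frozenset of allowed residues; ``None`` marks a
    wildcard (any of the 20 standard amino acids).
    """

    name: str
    classes: tuple[frozenset[str] | None, ...]
    side_condition: SideCondition | None = None
    pattern: str = ""

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise MotifError(f"motif {self.name!r}: pattern length must be >= 2")
        if self.side_condition is not None:
            for p in self.side_condition.positions:
                if not 1 <= p <= len(self.classes):
                    raise MotifError(
                        f"motif {self.name!r}: side-condition position {p} "
                        f"outside pattern length {len(self.classes)}"
                    )
                if self.classes[p - 1] is not None:
                    raise MotifError(
                        f"motif {self.name!r}: side-condition position {p} "
                        "is not a wildcard"
                    )

    def __len__(self) -> int:
        return len(self.classes)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.classes):
            return False
        for char, cls in zip(window, self.classes):
            if cls is None:
                if char not in AA20:  # 'X' and gaps fail wildcards too
                    return False
            elif char not in cls:
                return False
        if self.side_condition is not None and not self.side_condition.satisfied(window):
            return False
        return True


def parse_motif(
    name: str, pattern: str, side_condition: SideCondition | None = None
) -> MotifDefinition:
    """Parse a bracket-class pattern string such as ``"Hxxxx[ST]"``.

    Uppercase letters are fixed residues, ``x`` is a wildcard, and
    ``[...]`` encloses a residue set.
    """
    classes: list[frozenset[str] | None] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise MotifError(f"motif {name!r}: unclosed '[' in {pattern!r}")
            members = pattern[i + 1:j]
            if not members or set(members) - set(AA20):
                raise MotifError(f"motif {name!r}: bad residue class [{members}]")
            classes.append(frozenset(members))
            i = j + 1
        elif c == "x":
            classes.append(None)
            i += 1
        elif c in AA20:
            classes.append(frozenset(c))
            i += 1
        else:
            raise MotifError(f"motif {name!r}: bad pattern character {c!r}")
    return MotifDefinition(name, tuple(classes), side_condition, pattern)


CbkCentralMode = Literal["central", "any"]


def cbk1_phospho_motif(central: CbkCentralMode = "central") -> MotifDefinition:
    """Cbk1 phosphorylation consensus Hxxxx[ST] + basic side condition.

    ``central`` chooses which wildcards must carry the K/R: the middle two
    (positions 3-4, matching the kinase-consensus placement of the basic
    residue at -3 from the phosphosite) or any of the four.
    """
    positions = (3, 4) if central == "central" else (2, 3, 4, 5)
    return parse_motif(
        "cbk1_phospho", "Hxxxx[ST]",
        SideCondition(positions=positions, residues=frozenset("KR")),
    )


CBK1_PHOSPHO = cbk1_phospho_motif("central")
CBK1_DOCKING = parse_motif("cbk1_docking", "[YF]x[FP]")
ACTIVE_SITE = parse_motif("active_site", "DxxxxxDxDD")
#: positions of the magnesium-coordinating aspartates within the block
CATALYTIC_POSITIONS = (1, 9, 10)


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    motif: str
    start: int  # 1-based ungapped residue position
    matched: str


@dataclass(frozen=True)
class ActiveSiteCall:
    seq_id: str
    is_active_signature: bool
    residues_at_catalytic_columns: str  # 3 characters; '-' for gaps
    signature_window: str  # characters at the 10 anchored columns


@dataclass(frozen=True)
class NLSCall:
    seq_id: str
    has_nls: bool
    window_sequence: str
    basic_count: int


# ---------------------------------------------------------------------------
# Scanners
# ---------------------------------------------------------------------------

def scan_motif(seq: str, motif: MotifDefinition, seq_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) motif matches in a gap-free sequence."""
    if GAP in seq:
        raise MotifError("scan_motif requires a gap-free sequence")
    k = len(motif)
    hits = []
    for start in range(len(seq) - k + 1):
        window = seq[start:start + k]
        if motif.matches(window):
            hits.append(MotifHit(seq_id, motif.name, start + 1, window))
    return hits


def call_active_site(
    fam: AlignedFamily,
    anchor_id: str,
    anchor_motif_start: int,
    motif: MotifDefinition = ACTIVE_SITE,
    catalytic_positions: tuple[int, ...] = CATALYTIC_POSITIONS,
) -> list[ActiveSiteCall]:
    """Call the active-site signature for every row by column anchoring.

    The anchor must be a known active enzyme matching the active-site block
    at ``anchor_motif_start`` of its ungapped sequence; its motif residues
    locate the homologous alignment columns, and a row is an active
    signature iff all catalytic columns hold ``'D'`` (a gap at any catalytic
    column means inactive).
    """
    anchor_seq = fam.ungapped(anchor_id)
    k = len(motif)
    window = anchor_seq[anchor_motif_start - 1: anchor_motif_start - 1 + k]
    if len(window) < k or not motif.matches(window):
        raise MotifError(
            f"anchor {anchor_id!r} does not match {motif.pattern or motif.name} "
            f"at residue {anchor_motif_start} (found {window!r})"
        )
    cmap = build_column_map(fam, anchor_id)
    columns = [cmap.column(anchor_motif_start + p - 1) for p in range(1, k + 1)]
    if len(set(columns)) != k:
        raise MotifError("anchor motif residues do not map to distinct columns")
    cat_cols = [columns[p - 1] for p in catalytic_positions]
    calls = []
    for seq_id, row in fam:
        window_chars = "".join(row[c - 1] for c in columns)
        cat_chars = "".join(row[c - 1] for c in cat_cols)
        calls.append(
            ActiveSiteCall(
                seq_id=seq_id,
                is_active_signature=all(ch == "D" for ch in cat_chars),
                residues_at_catalytic_columns=cat_chars,
                signature_window=window_chars,
            )
        )
    return calls


def call_nls(
    fam: AlignedFamily,
    cmap: ColumnMap,
    nls_spec: DomainSpec,
    min_basic: int = 4,
) -> list[NLSCall]:
    """Count basic residues (K/R) in the mapped NLS window of each row.

    ``has_nls`` is true iff the count reaches ``min_basic`` (strict
    threshold: ``min_basic - 1`` basic residues is a negative call).
    """
    columns = cmap.columns_for(nls_spec)
    if not columns:
        raise FamilyError(f"NLS window {nls_spec} maps to zero columns")
    calls = []
    for seq_id, row in fam:
        window = "".join(row[c - 1] for c in columns).replace(GAP, "")
        basic = sum(1 for ch in window if ch in "KR")
        calls.append(NLSCall(seq_id, basic >= min_basic, window, basic))
    return calls


# ---------------------------------------------------------------------------
# Family-level annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationConfig:
    """Everything needed to build the per-sequence feature table."""

    anchor_id: str
    anchor_motif_start: int
    nterm: DomainSpec
    nls: DomainSpec
    min_basic: int = 4
    cbk1_central: CbkCentralMode = "central"
    active_site_motif: MotifDefinition = field(default_factory=lambda: ACTIVE_SITE)
    docking_motif: MotifDefinition = field(default_factory=lambda: CBK1_DOCKING)

    @property
    def phospho_motif(self) -> MotifDefinition:
        return cbk1_phospho_motif(self.cbk1_central)


def annotate_family(
    fam: AlignedFamily,
    cmap: ColumnMap,
    config: AnnotationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sequence feature table plus per-hit motif detail.

    Returns ``(features, hits)``. ``features`` has one row per sequence:
    id, active_site, nls, cbk1_phospho_count, cbk1_docking. Cbk1
    phosphorylation motifs are counted only within the configured
    N-terminal region (mapped through the reference); the docking call is
    positive on a hit anywhere in the full sequence. Overlapping hits are
    all counted.
    """
    active_calls = {
        c.seq_id: c
        for c in call_active_site(
            fam, config.anchor_id, config.anchor_motif_start, config.active_site_motif
        )
    }
    nls_calls = {
        c.seq_id: c for c in call_nls(fam, cmap, config.nls, config.min_basic)
    }
    phospho = config.phospho_motif
    nterm_cols = cmap.columns_for(config.nterm)
    col_set = set(nterm_cols)

    feat_rows = []
    hit_rows = []
    for seq_id, row in fam:
        # ungapped offset of the N-terminal region within this row
        before = sum(
            1 for c, ch in enumerate(row, start=1)
            if c < nterm_cols[0] and ch != GAP
        )
        region = "".join(
            ch for c, ch in enumerate(row, start=1) if c in col_set and ch != GAP
        )
        full = row.replace(GAP, "")
        phospho_hits = [
            MotifHit(seq_id, h.motif, h.start + before, h.matched)
            for h in scan_motif(region, phospho, seq_id)
        ]
        docking_hits = scan_motif(full, config.docking_motif, seq_id)
        hit_rows.extend(phospho_hits)
        hit_rows.extend(docking_hits)
        feat_rows.append(
            {
                "id": seq_id,
                "active_site": active_calls[seq_id].is_active_signature,
                "nls": nls_calls[seq_id].has_nls,
                "cbk1_phospho_count": len(phospho_hits),
                "cbk1_docking": bool(docking_hits),
            }
        )
    features = pd.DataFrame(feat_rows, columns=[
        "id", "active_site", "nls", "cbk1_phospho_count", "cbk1_docking"
    ])
    hits = pd.DataFrame(
        [(h.seq_id, h.motif, h.start, h.matched) for h in hit_rows],
        columns=["id", "motif", "start", "matched"],
    )
    return features, hits
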