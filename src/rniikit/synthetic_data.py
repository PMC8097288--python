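"""Simulation of protein families with planted domains, motifs, and losses.

The generator emulates the statistical structure of a fungal
Dis3L2/Ssd1-like family: ~100 sequences on a random Yule tree with an
outgroup clade; a domain architecture of a fast-evolving disordered
N-terminus, two highly conserved cold-shock domains (CSD1+2), a linker,
and a moderately conserved RNII catalytic domain; an RNII active-site
block ``DxxxxxDxDD`` that is lost irreversibly on random branches; and
planted Cbk1 phosphorylation motifs, a Cbk1 docking motif, and a basic
NLS window whose positions are held invariant so that planted feature
truth is exact.

Design choices
--------------
* Substitution model: per-site exponential waiting times with uniform
  replacement among the 19 alternative residues (a Jukes-Cantor-like
  model on amino acids) — controllable divergence, not realism.
* Background residues outside planted features are drawn from the 20
  amino acids minus {H, Y, F}, so the root sequence contains *only* the
  planted Cbk1 phosphorylation (needs H) and docking (needs Y/F) motifs;
  chance motifs can still arise later through substitution.
* Losses follow a Poisson process on branches, applied only while the
  lineage is still active; at a loss event the three catalytic aspartates
  are substituted to random non-D residues and stay fixed thereafter.
* Indels are off by default (exact coordinate truth); optionally,
  geometric-length deletions are placed in the N-terminal region only,
  skipping planted-feature positions.

All randomness flows through one ``numpy.random.Generator`` seeded from
the config, so a fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
import yaml

from .family_io import (
    AA20,
    AlignedFamily,
    DomainSpec,
    write_alignment,
    write_metadata,
    write_tree,
)
from .loss_reconstruction import ACTIVE, INACTIVE, _ensure_names, node_name

_AA = np.array(list(AA20))
_AA_INDEX = {a: i for i, a in enumerate(AA20)}
# background alphabet: no H (phospho start), no Y/F (docking)
_BACKGROUND = [i for a, i in _AA_INDEX.items() if a not in "HYF"]
_BASIC = [_AA_INDEX["K"], _AA_INDEX["R"]]
_BACKGROUND_NONBASIC = [i for i in _BACKGROUND if i not in _BASIC]
_NON_D = [i for a, i in _AA_INDEX.items() if a != "D"]


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class Blueprint:
    """Root-sequence architecture (defaults follow ScSsd1 coordinates).

    Domains: N-terminus 1..337, CSD1+2 338..659, linker 660..688,
    RNII 689..1014; total length 1014.
    """

    nterm_len: int = 337
    csd_len: int = 322
    linker_len: int = 29
    rnii_len: int = 326
    #: 1-based start of the DxxxxxDxDD block within the RNII domain
    active_site_offset: int = 192
    #: NLS window placed in a CSD1 loop: offset within the CSD region
    nls_offset: int = 73
    nls_len: int = 20
    nls_n_basic: int = 5
    n_cbk1_phospho: int = 7
    n_cbk1_docking: int = 1

    @property
    def total_len(self) -> int:
        return self.nterm_len + self.csd_len + self.linker_len + self.rnii_len

    @property
    def nterm(self) -> DomainSpec:
        return DomainSpec("Nterm", 1, self.nterm_len)

    @property
    def csd(self) -> DomainSpec:
        start = self.nterm_len + 1
        return DomainSpec("CSD1+2", start, start + self.csd_len - 1)

    @property
    def rnii(self) -> DomainSpec:
        start = self.nterm_len + self.csd_len + self.linker_len + 1
        return DomainSpec("RNII", start, start + self.rnii_len - 1)

    @property
    def active_site_start(self) -> int:
        return self.rnii.ref_start + self.active_site_offset - 1

    @property
    def catalytic_positions(self) -> tuple[int, int, int]:
        s = self.active_site_start
        return (s, s + 8, s + 9)

    @property
    def nls_window(self) -> DomainSpec:
        start = self.csd.ref_start + self.nls_offset - 1
        return DomainSpec("NLS", start, start + self.nls_len - 1)

    def validate(self) -> None:
        if self.active_site_offset + 9 > self.rnii_len:
            raise SimulationError("active-site block exceeds the RNII domain")
        if self.nls_offset + self.nls_len - 1 > self.csd_len:
            raise SimulationError("NLS window exceeds the CSD region")
        if self.nls_n_basic > self.nls_len:
            raise SimulationError("more basic NLS residues than window positions")
        if self.n_cbk1_phospho * 7 + self.n_cbk1_docking * 6 > self.nterm_len:
            raise SimulationError("too many planted motifs for the N-terminus")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated family."""

    n_tips: int = 100
    birth_rate: float = 1.0
    seed: int = 0
    blueprint: Blueprint = field(default_factory=Blueprint)
    # per-domain substitution rates (subs/site per unit branch length),
    # fast N-terminus >= RNII >= CSD
    rate_nterm: float = 0.4
    rate_csd: float = 0.03
    rate_rnii: float = 0.12
    rate_linker: float = 0.4
    #: loss events per unit branch length; default gives ~4 expected events
    #: on a 100-tip Yule tree (expected total length (n-1)/birth_rate)
    loss_rate: float = 0.04
    indel_rate: float = 0.0
    indel_mean_len: float = 3.0
    #: optional per-clade Cbk1 phosphorylation-motif counts (<= planted);
    #: the excess planted motifs are knocked out on those tips
    cbk1_clade_counts: dict[str, int] | None = None
    #: clades whose tips lose the docking motif
    docking_knockout_clades: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.n_tips < 2:
            raise SimulationError("n_tips must be >= 2")
        for name in ("birth_rate",):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        for name in ("rate_nterm", "rate_csd", "rate_rnii", "rate_linker",
                     "loss_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        self.blueprint.validate()
        if self.cbk1_clade_counts:
            for clade, count in self.cbk1_clade_counts.items():
                if not 0 <= count <= self.blueprint.n_cbk1_phospho:
                    raise SimulationError(
                        f"clade {clade!r}: Cbk1 count {count} outside "
                        f"0..{self.blueprint.n_cbk1_phospho}"
                    )


@dataclass
class SimTruth:
    """Ground truth for every downstream stage."""

    tree: dendropy.Tree
    newick: str
    loss_edges: list[tuple[str, str]]
    tip_states: dict[str, str]
    features: pd.DataFrame  # id, active_site, nls, cbk1_phospho_count, cbk1_docking
    clades: dict[str, str]  # tip id -> clade label
    metadata: pd.DataFrame
    root_sequence: str
    phospho_starts: list[int]  # 1-based planted motif starts on the reference
    docking_starts: list[int]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Yule trees
# ---------------------------------------------------------------------------

def expected_total_branch_length(n_tips: int, birth_rate: float) -> float:
    """E[sum of branch lengths] of the Yule trees produced here."""
    return (n_tips - 1) / birth_rate


def expected_depth(n_tips: int, birth_rate: float) -> float:
    """E[root-to-tip depth]: (H_n - 1) / birth_rate."""
    harmonic = sum(1.0 / k for k in range(1, n_tips + 1))
    return (harmonic - 1.0) / birth_rate


def simulate_tree(
    n_tips: int, birth_rate: float = 1.0, rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with ``n_tips`` extant tips.

    The process starts from two lineages at the root (no root stem edge)
    and runs one extra exponential interval after the last birth so that
    terminal branches have positive length. Tips are labelled ``t001``...
    in preorder.
    """
    if n_tips < 2:
        raise SimulationError("n_tips must be >= 2")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    first = [root.new_child(), root.new_child()]
    birth_time = {first[0]: 0.0, first[1]: 0.0}
    leaves = list(first)
    t = 0.0
    while len(leaves) < n_tips:
        k = len(leaves)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = leaves.pop(int(rng.integers(k)))
        node.edge.length = t - birth_time.pop(node)
        children = [node.new_child(), node.new_child()]
        for c in children:
            birth_time[c] = t
        leaves.extend(children)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for leaf in leaves:
        leaf.edge.length = t - birth_time[leaf]
    width = max(3, len(str(n_tips)))
    ns = tree.taxon_namespace
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            i += 1
            node.taxon = ns.new_taxon(label=f"t{i:0{width}d}")
    _ensure_names(tree)
    return tree


# ---------------------------------------------------------------------------
# loss process
# ---------------------------------------------------------------------------

def simulate_losses(
    tree: dendropy.Tree, loss_rate: float, rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Irreversible Poisson losses on branches of still-active lineages.

    An edge of length L carries a loss with probability ``1 - exp(-rate*L)``
    provided its parent lineage is still active; all descendant tips of a
    loss edge are inactive. Returns the loss edges (parent, child names)
    and the tip states.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    _ensure_names(tree)
    active: dict[dendropy.Node, bool] = {tree.seed_node: True}
    loss_edges: list[tuple[str, str]] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_active = active[node.parent_node]
        state = parent_active
        if parent_active:
            length = node.edge.length or 0.0
            if rng.random() < 1.0 - math.exp(-loss_rate * length):
                state = False
                loss_edges.append((node_name(node.parent_node), node_name(node)))
        active[node] = state
    tip_states = {
        node_name(leaf): (ACTIVE if active[leaf] else INACTIVE)
        for leaf in tree.leaf_node_iter()
    }
    return loss_edges, tip_states


# ---------------------------------------------------------------------------
# clade labelling
# ---------------------------------------------------------------------------

def assign_clades(tree: dendropy.Tree) -> dict[str, str]:
    """Label tips: the smaller side of the root is the outgroup clade; the
    other side's immediate subtrees become clades A, B, C, ..."""
    root_children = tree.seed_node.child_nodes()
    sides = sorted(root_children, key=lambda n: len(n.leaf_nodes()))
    outgroup, ingroup = sides[0], sides[-1]
    clades: dict[str, str] = {}
    for leaf in outgroup.leaf_iter():
        clades[node_name(leaf)] = "outgroup"
    if ingroup.is_leaf():
        clades[node_name(ingroup)] = "cladeA"
    else:
        for i, child in enumerate(ingroup.child_nodes()):
            label = f"clade{chr(ord('A') + i)}"
            for leaf in child.leaf_iter():
                clades[node_name(leaf)] = label
    return clades


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _build_root(
    bp: Blueprint, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[int], list[int]]:
    """Root sequence (index array), mask of invariant positions, and the
    planted phospho/docking motif starts (1-based)."""
    n = bp.total_len
    seq = rng.choice(_BACKGROUND, size=n)
    mask = np.zeros(n, dtype=bool)

    # active-site block DxxxxxDxDD (0-based start)
    s = bp.active_site_start - 1
    block = seq[s:s + 10].copy()
    for off in (0, 6, 8, 9):
        block[off] = _AA_INDEX["D"]
    seq[s:s + 10] = block
    mask[s:s + 10] = True

    # NLS window: exactly nls_n_basic K/R among non-basic background
    w = bp.nls_window
    window = rng.choice(_BACKGROUND_NONBASIC, size=bp.nls_len)
    basic_pos = rng.choice(bp.nls_len, size=bp.nls_n_basic, replace=False)
    window[basic_pos] = rng.choice(_BASIC, size=bp.nls_n_basic)
    seq[w.ref_start - 1:w.ref_end] = window
    mask[w.ref_start - 1:w.ref_end] = True

    # non-overlapping motif slots in the N-terminus (1-based starts);
    # docking gets a 5-wide slot so the two residues after it can be fixed
    slots: list[tuple[int, int]] = []

    def place(length: int) -> int:
        for _ in range(10_000):
            start = int(rng.integers(1, bp.nterm_len - length + 2))
            if all(start + length - 1 < a or start > b for a, b in slots):
                slots.append((start, start + length - 1))
                return start
        raise SimulationError("could not place non-overlapping motifs")

    phospho_starts = sorted(place(6) for _ in range(bp.n_cbk1_phospho))
    docking_starts = sorted(place(5) for _ in range(bp.n_cbk1_docking))

    for p in phospho_starts:
        i = p - 1
        seq[i] = _AA_INDEX["H"]
        # positions 2..5 background; one central position (3 or 4) basic
        central = int(rng.integers(2, 4))  # motif position 3 or 4
        seq[i + central] = rng.choice(_BASIC)
        seq[i + 5] = _AA_INDEX["S"] if rng.random() < 0.5 else _AA_INDEX["T"]
        mask[i:i + 6] = True
    for p in docking_starts:
        i = p - 1
        seq[i] = _AA_INDEX["Y"]
        seq[i + 2] = _AA_INDEX["F"]
        # keep the trailing F from seeding a second [YF]x[FP] window
        if i + 4 < n and seq[i + 4] == _AA_INDEX["P"]:
            seq[i + 4] = _AA_INDEX["A"]
        mask[i:i + 5] = True
    return seq, mask, phospho_starts, docking_starts


def _site_rates(cfg: SimulationConfig, mask: np.ndarray) -> np.ndarray:
    bp = cfg.blueprint
    rates = np.empty(bp.total_len)
    rates[bp.nterm.ref_start - 1:bp.nterm.ref_end] = cfg.rate_nterm
    rates[bp.csd.ref_start - 1:bp.csd.ref_end] = cfg.rate_csd
    rates[bp.csd.ref_end:bp.rnii.ref_start - 1] = cfg.rate_linker
    rates[bp.rnii.ref_start - 1:bp.rnii.ref_end] = cfg.rate_rnii
    rates[mask] = 0.0
    return rates


def _mutate(
    seq: np.ndarray, rates: np.ndarray, t: float, rng: np.random.Generator
) -> np.ndarray:
    """Jukes-Cantor-like substitution along one branch of length t."""
    child = seq.copy()
    counts = rng.poisson(rates * t)
    for site in np.nonzero(counts)[0]:
        cur = int(child[site])
        for _ in range(int(counts[site])):
            step = int(rng.integers(19))
            cur = step if step < cur else step + 1
        child[site] = cur
    return child


def evolve_family(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AlignedFamily, SimTruth]:
    """Evolve a family down a tree, returning the alignment and full truth.

    With a zero indel rate the alignment is gap-free and column i equals
    reference residue i for every row, so coordinate truth is exact.
    """
    config.validate()
    bp = config.blueprint
    if rng is None:
        rng = np.random.default_rng(config.seed)
    _ensure_names(tree)

    loss_edges, tip_states = simulate_losses(tree, config.loss_rate, rng)
    loss_children = {child for _, child in loss_edges}

    root_seq, mask, phospho_starts, docking_starts = _build_root(bp, rng)
    rates = _site_rates(config, mask)
    cat_idx = np.array([p - 1 for p in bp.catalytic_positions])

    seqs: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root_seq}
    deletions: dict[dendropy.Node, np.ndarray] = {
        tree.seed_node: np.zeros(bp.total_len, dtype=bool)
    }
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        child = _mutate(seqs[node.parent_node], rates, t, rng)
        if node_name(node) in loss_children:
            child[cat_idx] = rng.choice(_NON_D, size=len(cat_idx))
        dele = deletions[node.parent_node].copy()
        if config.indel_rate > 0:
            for _ in range(int(rng.poisson(config.indel_rate * t))):
                length = int(rng.geometric(1.0 / config.indel_mean_len))
                start = int(rng.integers(bp.nterm_len))
                stop = min(start + length, bp.nterm_len)
                if mask[start:stop].any():
                    continue  # planted features stay intact
                dele[start:stop] = True
        seqs[node] = child
        deletions[node] = dele

    clades = assign_clades(tree)
    knockouts = _apply_knockouts(
        tree, seqs, config, phospho_starts, docking_starts, clades
    )

    rows = []
    feat_rows = []
    meta_rows = []
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        tip = node_name(leaf)
        chars = _AA[seqs[leaf]]
        aligned = chars.copy()
        aligned[deletions[leaf]] = "-"
        rows.append((tip, "".join(aligned)))
        n_phospho, has_docking = knockouts[tip]
        nls_window = "".join(
            chars[bp.nls_window.ref_start - 1:bp.nls_window.ref_end]
        )
        basic = sum(1 for ch in nls_window if ch in "KR")
        feat_rows.append({
            "id": tip,
            "active_site": tip_states[tip] == ACTIVE,
            "nls": basic >= 4,
            "cbk1_phospho_count": n_phospho,
            "cbk1_docking": has_docking,
        })
        meta_rows.append({
            "id": tip,
            "species": f"Simulated species {i}",
            "clade": clades[tip],
        })

    metadata = pd.DataFrame(meta_rows, columns=["id", "species", "clade"])
    fam = AlignedFamily(rows, metadata=metadata)
    features = pd.DataFrame(feat_rows, columns=[
        "id", "active_site", "nls", "cbk1_phospho_count", "cbk1_docking"
    ])
    truth = SimTruth(
        tree=tree,
        newick=tree.as_string(schema="newick", unquoted_underscores=True),
        loss_edges=loss_edges,
        tip_states=tip_states,
        features=features,
        clades=clades,
        metadata=metadata,
        root_sequence="".join(_AA[root_seq]),
        phospho_starts=phospho_starts,
        docking_starts=docking_starts,
        config=config,
    )
    return fam, truth


def _apply_knockouts(
    tree: dendropy.Tree,
    seqs: dict[dendropy.Node, np.ndarray],
    config: SimulationConfig,
    phospho_starts: list[int],
    docking_starts: list[int],
    clades: dict[str, str],
) -> dict[str, tuple[int, bool]]:
    """Reduce planted motif counts on configured clades.

    Excess phosphorylation motifs lose their H (-> A); docking knockouts
    lose the Y. Returns per-tip (phospho count, docking present)."""
    bp = config.blueprint
    out: dict[str, tuple[int, bool]] = {}
    counts = config.cbk1_clade_counts or {}
    no_dock = set(config.docking_knockout_clades)
    ala = _AA_INDEX["A"]
    for leaf in tree.leaf_node_iter():
        tip = node_name(leaf)
        clade = clades[tip]
        target = counts.get(clade, bp.n_cbk1_phospho)
        for start in phospho_starts[target:]:
            seqs[leaf][start - 1] = ala
        docking = bp.n_cbk1_docking > 0 and clade not in no_dock
        if not docking:
            for start in docking_starts:
                seqs[leaf][start - 1] = ala
        out[tip] = (target, docking)
    return out


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def anchor_for(truth: SimTruth, fam: AlignedFamily | None = None) -> tuple[str, int]:
    """A (tip id, motif start) pair usable to anchor active-site calls:
    the first active tip in preorder. With indels off the block starts at
    the blueprint's reference coordinate; when an alignment is supplied
    the ungapped start is computed from the tip's own row (deletions
    upstream of the block shift residue numbering)."""
    ref_start = truth.config.blueprint.active_site_start
    for leaf in truth.tree.leaf_node_iter():
        tip = node_name(leaf)
        if truth.tip_states[tip] == ACTIVE:
            if fam is None:
                return tip, ref_start
            row = fam[tip]
            # columns equal reference positions (deletions keep columns)
            start = sum(1 for ch in row[:ref_start - 1] if ch != "-") + 1
            return tip, start
    raise SimulationError("no active tip available to anchor on")


def write_fixture(
    fam: AlignedFamily, truth: SimTruth, outdir: str | Path
) -> Path:
    """Write a directory consumable by the analysis pipeline.

    Contents: alignment.fasta, tree.nwk, metadata.tsv, truth_features.tsv,
    truth_losses.tsv, and config.yaml pre-filled with the blueprint's
    domain coordinates and a valid anchor.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_alignment(fam, outdir / "alignment.fasta")
    write_tree(truth.tree, outdir / "tree.nwk")
    write_metadata(truth.metadata, outdir / "metadata.tsv")
    truth.features.to_csv(outdir / "truth_features.tsv", sep="\t", index=False)
    pd.DataFrame(truth.loss_edges, columns=["parent", "child"]).to_csv(
        outdir / "truth_losses.tsv", sep="\t", index=False
    )
    bp = truth.config.blueprint
    anchor_id, anchor_start = anchor_for(truth, fam)
    # blueprint domain coordinates apply to a gap-free reference row
    reference_id = next(
        (i for i in fam.ids if "-" not in fam[i]), anchor_id
    )
    outgroup = sorted(
        tip for tip, clade in truth.clades.items() if clade == "outgroup"
    )
    cfg = {
        "alignment": "alignment.fasta",
        "tree": "tree.nwk",
        "metadata": "metadata.tsv",
        "reference_id": reference_id,
        "anchor_id": anchor_id,
        "anchor_motif_start": anchor_start,
        "domains": {
            "Nterm": [bp.nterm.ref_start, bp.nterm.ref_end],
            "CSD1+2": [bp.csd.ref_start, bp.csd.ref_end],
            "RNII": [bp.rnii.ref_start, bp.rnii.ref_end],
        },
        "nls_window": [bp.nls_window.ref_start, bp.nls_window.ref_end],
        "min_basic": 4,
        "gap_threshold": 0.1,
        "trim_domains": True,
        "cbk1_central": "central",
        "outgroup": outgroup,
        "reconstruction_mode": "dollo",
        "seed": truth.config.seed,
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    return outdir


def simulate_family(
    config: SimulationConfig | None = None, **overrides
) -> tuple[AlignedFamily, SimTruth]:
    """Convenience wrapper: tree + losses + sequences in one call."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_tips, config.birth_rate, rng)
    return evolve_family(tree, config, rng)
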