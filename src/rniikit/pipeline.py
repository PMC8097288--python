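"""End-to-end orchestration: trim -> map -> annotate -> conserve -> reconstruct.

A :class:`PipelineConfig` (plain YAML, key: value with nested sections)
names the input alignment, tree, and optional metadata, the reference
sequence and its domain coordinates, the motif/NLS settings, the
outgroup, and the reconstruction mode. :func:`run_pipeline` validates the
config up front, runs every stage deterministically, and writes a run
directory:

    feature_table.tsv   per-sequence feature calls
    motif_hits.tsv      per-hit motif detail
    identity_<dom>.tsv  pairwise percent identity (wide), tree-tip order
    identity_long.tsv   all domains, long form
    consensus_profile.tsv  active-site window residue probabilities
    loss_report.tsv     loss edges of the reconstruction
    annotated.nwk       input tree with loss edges annotated
    kept_columns_<dom>.tsv  trimmed-to-untrimmed coordinate translation
    resolved_config.yaml   every default actually applied
    run_log.txt         stage-by-stage log (no timestamps: reruns are
                        byte-identical)

Every output table carries a provenance header comment with the tool
version, the seed, and a hash of the resolved configuration. Analysis
stages use no randomness; the seed only matters for the simulator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .family_io import (
    AlignedFamily,
    DomainSpec,
    build_column_map,
    extract_domain,
    read_alignment,
    read_metadata,
    read_tree,
    trim_columns,
    write_kept_columns,
)
from .motif_annotation import AnnotationConfig, annotate_family
from .domain_conservation import (
    consensus_profile,
    pairwise_identity,
    signature_string,
)
from .loss_reconstruction import (
    map_losses,
    root_on_outgroup,
    tip_labels,
)
from .synthetic_data import SimulationConfig, simulate_family, write_fixture


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


_DEFAULT_DOMAINS = {"Nterm": (1, 337), "CSD1+2": (338, 659), "RNII": (689, 1014)}


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; unset fields take the documented defaults."""

    alignment: Path
    tree: Path
    reference_id: str
    anchor_id: str
    anchor_motif_start: int
    nls_window: tuple[int, int]
    metadata: Path | None = None
    domains: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_DOMAINS)
    )
    conservation_domains: tuple[str, ...] = ("CSD1+2", "RNII")
    gap_threshold: float = 0.1
    trim_domains: bool = True
    min_basic: int = 4
    cbk1_central: str = "central"
    signature_major: float = 0.9
    signature_minor: float = 0.5
    outgroup: tuple[str, ...] = ()
    reconstruction_mode: str = "dollo"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def respath(key: str) -> Path | None:
            if raw.get(key) is None:
                return None
            p = Path(raw[key])
            return p if p.is_absolute() else base / p

        kwargs: dict = {
            "alignment": respath("alignment"),
            "tree": respath("tree"),
            "metadata": respath("metadata"),
            "reference_id": raw["reference_id"],
            "anchor_id": raw["anchor_id"],
            "anchor_motif_start": int(raw["anchor_motif_start"]),
            "nls_window": tuple(raw["nls_window"]),
        }
        if "domains" in raw:
            kwargs["domains"] = {k: tuple(v) for k, v in raw["domains"].items()}
        for key in (
            "conservation_domains", "gap_threshold", "trim_domains", "min_basic",
            "cbk1_central", "signature_major", "signature_minor", "outgroup",
            "reconstruction_mode", "seed",
        ):
            if key in raw:
                value = raw[key]
                if key in ("outgroup", "conservation_domains"):
                    value = tuple(value)
                kwargs[key] = value
        return cls(**kwargs)

    def resolved(self) -> dict:
        d = {
            "alignment": str(self.alignment),
            "tree": str(self.tree),
            "metadata": None if self.metadata is None else str(self.metadata),
            "reference_id": self.reference_id,
            "anchor_id": self.anchor_id,
            "anchor_motif_start": self.anchor_motif_start,
            "nls_window": list(self.nls_window),
            "domains": {k: list(v) for k, v in self.domains.items()},
            "conservation_domains": list(self.conservation_domains),
            "gap_threshold": self.gap_threshold,
            "trim_domains": self.trim_domains,
            "min_basic": self.min_basic,
            "cbk1_central": self.cbk1_central,
            "signature_major": self.signature_major,
            "signature_minor": self.signature_minor,
            "outgroup": list(self.outgroup),
            "reconstruction_mode": self.reconstruction_mode,
            "seed": self.seed,
            "version": __version__,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        for name in ("alignment", "tree"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise PipelineError("validate", f"{name} file not found: {p}")
        if self.metadata is not None and not Path(self.metadata).exists():
            raise PipelineError("validate", f"metadata file not found: {self.metadata}")
        if self.reconstruction_mode not in ("dollo", "fitch"):
            raise PipelineError(
                "validate", f"unknown reconstruction mode {self.reconstruction_mode!r}"
            )
        for name, (a, b) in self.domains.items():
            DomainSpec(name, a, b)  # raises on bad ranges
        DomainSpec("NLS", *self.nls_window)
        for name in self.conservation_domains:
            if name not in self.domains:
                raise PipelineError("validate", f"conservation domain {name!r} undefined")


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    with path.open("w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all analysis stages and write the run directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = (
        f"# rniikit {__version__} | config_hash={chash} | seed={config.seed}\n"
    )
    log: list[str] = [f"rniikit {__version__} run (config_hash={chash})"]

    def stage(name: str):
        log.append(f"[stage] {name}")

    try:
        stage("load")
        metadata = (
            read_metadata(config.metadata) if config.metadata is not None else None
        )
        fam = read_alignment(config.alignment, metadata=metadata)
        tree = read_tree(config.tree)
        log.append(f"alignment: {len(fam)} rows x {fam.n_columns} columns")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError("load", str(exc)) from exc

    try:
        stage("map")
        cmap = build_column_map(fam, config.reference_id)
        log.append(
            f"reference {config.reference_id}: {cmap.ref_length} residues"
        )
    except Exception as exc:
        raise PipelineError("map", str(exc)) from exc

    try:
        stage("annotate")
        nterm = DomainSpec("Nterm", *config.domains["Nterm"])
        ann_cfg = AnnotationConfig(
            anchor_id=config.anchor_id,
            anchor_motif_start=config.anchor_motif_start,
            nterm=nterm,
            nls=DomainSpec("NLS", *config.nls_window),
            min_basic=config.min_basic,
            cbk1_central=config.cbk1_central,  # type: ignore[arg-type]
        )
        features, hits = annotate_family(fam, cmap, ann_cfg)
        _write_table(features, outdir / "feature_table.tsv", header)
        _write_table(hits, outdir / "motif_hits.tsv", header)
        log.append(
            f"features: {int(features['active_site'].sum())} active-signature "
            f"of {len(features)} sequences; min_basic={config.min_basic} "
            f"(default 4), cbk1_central={config.cbk1_central!r}"
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("annotate", str(exc)) from exc

    try:
        stage("conserve")
        order = [t for t in tip_labels(tree) if t in fam]
        long_frames = []
        for name in config.conservation_domains:
            spec = DomainSpec(name, *config.domains[name])
            dom = extract_domain(fam, cmap, spec)
            if config.trim_domains:
                dom, kept = trim_columns(dom, config.gap_threshold)
                write_kept_columns(
                    kept, outdir / f"kept_columns_{_slug(name)}.tsv"
                )
                log.append(
                    f"domain {name}: trimmed to {len(kept)} columns at "
                    f"gap threshold {config.gap_threshold} (inclusive >=)"
                )
            mat = pairwise_identity(dom, domain_name=name)
            if set(order) == set(mat.ids):
                mat = mat.reorder(order)
            wide = mat.to_dataframe().reset_index().rename(columns={"index": "id"})
            _write_table(wide, outdir / f"identity_{_slug(name)}.tsv", header)
            long_frames.append(mat.to_long())
            log.append(
                f"domain {name}: mean pairwise identity "
                f"{mat.mean_offdiagonal():.2f}%"
            )
        _write_table(
            pd.concat(long_frames, ignore_index=True),
            outdir / "identity_long.tsv", header,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("conserve", str(exc)) from exc

    try:
        stage("consensus")
        anchor_map = build_column_map(fam, config.anchor_id)
        start = config.anchor_motif_start
        window_cols = [anchor_map.column(start + i) for i in range(10)]
        profile = consensus_profile(fam, window_cols)
        _write_table(
            profile.to_long(), outdir / "consensus_profile.tsv", header
        )
        sig = signature_string(
            profile, config.signature_major, config.signature_minor
        )
        log.append(
            f"active-site window signature: {sig} "
            f"(major>={config.signature_major}, minor>={config.signature_minor})"
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("consensus", str(exc)) from exc

    try:
        stage("reconstruct")
        if config.outgroup:
            tree = root_on_outgroup(tree, config.outgroup)
            log.append(f"rooted on outgroup of {len(config.outgroup)} tips")
        report, annotated = map_losses(
            tree, features, mode=config.reconstruction_mode
        )
        _write_table(report.to_dataframe(), outdir / "loss_report.tsv", header)
        (outdir / "annotated.nwk").write_text(
            annotated.as_string(
                schema="newick", unquoted_underscores=True,
                suppress_annotations=False,
            )
        )
        log.append(
            f"{report.reconstruction_mode}: {report.n_independent_losses} "
            f"independent losses ({report.min_changes} changes; "
            f"ambiguous={report.ambiguous})"
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("reconstruct", str(exc)) from exc

    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=False)
    )
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return outdir


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name).strip("_")


def run_simulation(
    sim_config: SimulationConfig, outdir: str | Path
) -> Path:
    """Simulate a family and write a fixture directory run_pipeline accepts."""
    fam, truth = simulate_family(sim_config)
    return write_fixture(fam, truth, outdir)
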