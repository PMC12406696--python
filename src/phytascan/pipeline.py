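"""End-to-end orchestration: build-db → search → screen → quantify.

A single validated configuration drives the stages in order; every stage
writes plain-text TSV outputs with provenance header comments (config hash,
seed, package version — no timestamps, so reruns are byte-identical), and a
completed stage is skipped on rerun unless forced. Defaults: E-value cutoff
1e-30, clade identity threshold 0.28, ten universal marker genes for
normalization.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._io import read_fasta, read_tsv, write_tsv
from .abundance import DEFAULT_MARKER_GENES, normalize_to_markers
from .catalog import cluster_into_clades, load_catalog
from .profiles import build_profile, calibrate_evalues, search_profiles
from .screen import screen_candidates

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    query_fasta: str = ""
    outdir: str = "phytascan_out"
    catalog: str | None = None  # None -> bundled catalog
    reference_fasta: str | None = None  # None -> synthetic stand-ins
    gene_counts: str | None = None
    marker_counts: str | None = None
    evalue_cutoff: float = 1e-30
    identity_threshold: float = 0.28
    marker_genes: list[str] = field(default_factory=lambda: list(DEFAULT_MARKER_GENES))
    pseudocount: float = 1.0
    tolerance_window: int = 10
    min_motifs: int | None = None
    calibration_n: int = 300
    nst_reps: int = 1000
    seed: int = 42
    force: bool = False

    def config_hash(self) -> str:
        # outdir and force do not change the analysis, only where/whether
        # files are written; reruns elsewhere stay byte-identical
        payload = {k: v for k, v in asdict(self).items() if k not in ("force", "outdir")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def provenance(self) -> dict[str, object]:
        return {
            "phytascan_version": __version__,
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "evalue_cutoff": self.evalue_cutoff,
            "identity_threshold": self.identity_threshold,
        }


_COERCERS = {
    float: float,
    int: int,
    bool: lambda v: v if isinstance(v, bool) else str(v).lower() in ("1", "true", "yes"),
}


def validate_config(source: "str | Path | dict | None") -> PipelineConfig:
    """Normalize a config mapping or YAML file into a PipelineConfig.

    Unknown keys are rejected with a spelling suggestion; numeric strings
    (e.g. ``evalue_cutoff: "1e-30"``) are coerced.
    """
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        import yaml

        text = Path(source).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise PipelineError("config file must contain a key: value mapping")
    defaults = PipelineConfig()
    known = set(asdict(defaults))
    for key in data:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise PipelineError(f"unknown config key {key!r}{suffix}")
    kwargs = {}
    for key, value in data.items():
        default = getattr(defaults, key)
        if value is not None and default is not None and not isinstance(value, type(default)):
            coercer = _COERCERS.get(type(default))
            if coercer is not None:
                try:
                    value = coercer(value)
                except (TypeError, ValueError) as exc:
                    raise PipelineError(f"config key {key!r}: {exc}") from exc
        kwargs[key] = value
    return PipelineConfig(**kwargs)


def _build_db(config: PipelineConfig):
    catalog = load_catalog(config.catalog)
    if config.reference_fasta:
        seqs = read_fasta(config.reference_fasta)
        missing = [e.accession for e in catalog if e.accession not in seqs]
        if missing:
            raise PipelineError(f"build-db: reference FASTA lacks sequences for {missing}")
        enzymes = [e.with_sequence(seqs[e.accession]) for e in catalog]
    else:
        from .synthetic import attach_synthetic_sequences

        enzymes = attach_synthetic_sequences(catalog)
    clades = cluster_into_clades(enzymes, config.identity_threshold)
    by_acc = {e.accession: e for e in enzymes}
    reps = {}
    profiles = []
    calibrations = {}
    for clade in clades:
        rep = by_acc[clade.representative]
        reps[rep.clade_id] = rep
        profile = build_profile(
            [rep.sequence], config.pseudocount,
            clade_label=rep.clade_id, family=rep.family,
        )
        profiles.append(profile)
        calibrations[rep.clade_id] = calibrate_evalues(
            profile, n_random=config.calibration_n, seed=config.seed
        )
    return enzymes, clades, reps, profiles, calibrations


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns a summary with per-stage counts.

    Any stage failure raises :class:`PipelineError` naming the stage; outputs
    written by completed stages are preserved alongside a partial manifest.
    """
    outdir = Path(config.outdir)
    if not config.query_fasta or not Path(config.query_fasta).exists():
        raise PipelineError(f"validation: query FASTA not found: {config.query_fasta!r}")
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = config.provenance()
    manifest: dict[str, str] = {}
    summary: dict[str, object] = {"config_hash": config.config_hash()}

    def _stage(name, path, producer):
        """Run one stage unless its output already exists (idempotency)."""
        target = outdir / path
        if target.exists() and not config.force:
            logger.info("stage %s: output exists, skipping (use force to rerun)", name)
            return None
        try:
            frame = producer()
        except PipelineError:
            raise
        except Exception as exc:
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(f"{name}: {exc}") from exc
        write_tsv(frame, target, provenance)
        manifest[name] = str(target)
        return frame

    enzymes, clades, reps, profiles, calibrations = _build_db(config)
    clade_frame = pd.DataFrame(
        [
            {
                "clade": c.clade_id,
                "family": c.family,
                "representative": c.representative,
                "n_members": len(c.members),
                "members": ",".join(sorted(c.members)),
            }
            for c in clades
        ]
    )
    _stage("build-db", "clades.tsv", lambda: clade_frame)
    summary["clades"] = len(clades)

    proteins = read_fasta(config.query_fasta)
    hits = search_profiles(profiles, proteins, config.evalue_cutoff, calibrations)
    hits_frame = pd.DataFrame(
        [
            {
                "query": h.query_id, "clade": h.clade_label, "family": h.family,
                "score_bits": round(h.score_bits, 4), "e_value": f"{h.e_value:.3e}",
                "qstart": h.qstart, "qend": h.qend,
            }
            for h in hits
        ],
        columns=["query", "clade", "family", "score_bits", "e_value", "qstart", "qend"],
    )
    _stage("search", "hits.tsv", lambda: hits_frame)
    summary["candidates"] = len(hits)

    results = screen_candidates(
        hits, proteins, reps, config.tolerance_window, config.min_motifs
    )
    screen_frame = pd.DataFrame(
        [
            {
                "query": r.query_id, "clade": r.clade_label,
                "qualified": r.qualified, "reason": r.reason,
                "motifs_found": ";".join(
                    f"{c.pattern}@{c.candidate_start}" for c in r.motif_checks if c.found
                ),
            }
            for r in results
        ],
        columns=["query", "clade", "qualified", "reason", "motifs_found"],
    )
    _stage("screen", "screen.tsv", lambda: screen_frame)
    qualified = [r for r in results if r.qualified]
    summary["qualified"] = len(qualified)
    per_family: dict[str, int] = {}
    for r in qualified:
        fam = r.clade_label.split("_")[0]
        per_family[fam] = per_family.get(fam, 0) + 1
    summary["qualified_per_family"] = per_family

    if config.gene_counts and config.marker_counts:
        gene = read_tsv(config.gene_counts, index_col=0)
        marker = read_tsv(config.marker_counts, index_col=0)
        table = normalize_to_markers(gene, marker, n_markers=len(config.marker_genes))
        _stage("quantify", "abundance.tsv", lambda: table.values.reset_index(names="sample"))
        summary["samples_quantified"] = len(table.samples)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    summary["manifest"] = manifest
    return summary
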