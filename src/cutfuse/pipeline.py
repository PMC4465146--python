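"""Configurable end-to-end pipeline tying the analysis stages together.

Each run stage is a pure composition of the library functions (no hidden
state), so pipeline output equals running the stages by hand on the same
inputs.  All randomness flows through seeds named in the config; outputs are
byte-identical across runs except for the timestamp line in the run log.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .guides import GuideSpec, find_guide_sites
from .io import (
    read_fasta,
    read_fastq,
    write_amplicons_tsv,
    write_fasta,
    write_fastq,
    write_sam,
    write_spectrum_tsv,
)
from .junctions import (
    DELETION,
    INVERSION,
    JunctionRef,
    PrimerPair,
    RearrangementEvent,
    apply_deletion,
    apply_inversion,
    insilico_pcr,
    predict_junctions,
)
from .quant import Scoring, align_reads, build_report, filter_observations
from .repair import NHEJ_ERROR, RepairMode, explain_indel
from .seqs import NucSeq
from .simdata import ReadSimSpec, make_fixture, simulate_reads

log = logging.getLogger("cutfuse")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_EMPTY = 3


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2)."""


@dataclass
class PipelineConfig:
    """Validated pipeline parameters (see ``from_yaml``)."""

    reference: str
    guide_a: str
    guide_b: str
    guides: dict[str, str]
    outdir: str = "cutfuse_out"
    pam_classes: tuple[str, ...] = ("NGG", "NAG")
    primers: dict[str, dict[str, str]] = field(default_factory=dict)
    kinds: tuple[str, ...] = (DELETION, INVERSION)
    offset_min: int = 3
    offset_max: int = 8
    flank: int = 100
    fusion_window: int = 20
    scoring: Scoring = field(default_factory=Scoring)
    identity_floor: float = 0.8
    min_freq: float = 0.01
    min_var_reads: int = 2
    error_rate: float = 0.01
    seed: int = 0
    max_amplicon: int = 10000
    write_sam: bool = False
    sample: str = "sample"
    replicate: str = "1"

    def __post_init__(self) -> None:
        if not 3 <= self.offset_min <= self.offset_max <= 8:
            raise ConfigError("offsets must satisfy 3 <= min <= max <= 8")
        if not 0 <= self.min_freq <= 1:
            raise ConfigError("min_freq must be in [0, 1]")
        if self.min_var_reads < 0:
            raise ConfigError("min_var_reads must be >= 0")
        if not 0 < self.error_rate < 0.5:
            raise ConfigError("error_rate must be in (0, 0.5)")
        for k in self.kinds:
            if k not in (DELETION, INVERSION):
                raise ConfigError(f"unknown event kind {k!r}")
        for g in (self.guide_a, self.guide_b):
            if g not in self.guides:
                raise ConfigError(f"guide {g!r} not defined under 'guides'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "scoring" in raw and isinstance(raw["scoring"], dict):
            raw["scoring"] = Scoring(**raw["scoring"])
        for key in ("kinds", "pam_classes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        if not Path(cfg.reference).exists():
            raise ConfigError(f"reference file not found: {cfg.reference}")
        return cfg

    @property
    def offsets(self) -> range:
        return range(self.offset_min, self.offset_max + 1)


def _load_reference(config: PipelineConfig) -> NucSeq:
    seqs = read_fasta(config.reference)
    if not seqs:
        raise ConfigError(f"no sequences in {config.reference}")
    return seqs[0]


def _resolve_sites(config: PipelineConfig, ref: NucSeq):
    def one_site(name: str):
        guide = GuideSpec(name, config.guides[name])
        sites = find_guide_sites(ref, guide, config.pam_classes)
        if not sites:
            raise ConfigError(f"no target site found for guide {name!r}")
        return sites[0]

    if config.guide_a == config.guide_b:
        guide = GuideSpec(config.guide_a, config.guides[config.guide_a])
        sites = find_guide_sites(ref, guide, config.pam_classes)
        if len(sites) < 2:
            raise ConfigError(
                f"guide {config.guide_a!r} must cut twice but has "
                f"{len(sites)} site(s)"
            )
        return sites[0], sites[1]
    return one_site(config.guide_a), one_site(config.guide_b)


def _write_log(outdir: Path, config: PipelineConfig, extra: dict) -> None:
    lines = [f"# cutfuse {__version__} run log"]
    lines.append(f"timestamp: {datetime.now(timezone.utc).isoformat()}")
    for k, v in sorted(vars(config).items()):
        lines.append(f"{k}: {v}")
    for k, v in extra.items():
        lines.append(f"{k}: {v}")
    (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")


def run_predict(config: PipelineConfig) -> dict[str, list[JunctionRef]]:
    """Predict canonical junctions and in-silico PCR sizes; write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = _load_reference(config)
    site_a, site_b = _resolve_sites(config, ref)

    junctions: dict[str, list[JunctionRef]] = {}
    all_jrs = []
    templates: list[NucSeq] = [ref.replace(name=ref.name + "_unedited")]
    for kind in config.kinds:
        jrs = predict_junctions(ref, site_a, site_b, kind, flank=config.flank)
        junctions[kind] = jrs
        all_jrs.extend(jrs)
        event = jrs[0].event
        edited = (
            apply_deletion(ref, event) if kind == DELETION else apply_inversion(ref, event)
        )
        templates.append(edited)
    write_fasta([j.sequence for j in all_jrs], outdir / "junctions.fasta")
    write_fasta(templates, outdir / "templates.fasta")

    amp_rows = []
    for tmpl in templates:
        for pname, pdict in config.primers.items():
            pair = PrimerPair(pdict["forward"], pdict["reverse"], pname)
            for amp in insilico_pcr(tmpl, pair, config.max_amplicon):
                amp_rows.append((tmpl.name, pname, amp))
    write_amplicons_tsv(amp_rows, outdir / "amplicons.tsv")
    _write_log(outdir, config, {"stage": "predict", "n_junctions": len(all_jrs)})
    return junctions


def run_quantify(config: PipelineConfig, fastq: str | Path) -> list:
    """Align reads to each predicted junction and write spectrum reports.

    Each read is assigned to its best-scoring mapped junction.  Returns the
    list of (filtered) SpectrumReports; exit-code semantics are handled by
    the CLI layer.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = _load_reference(config)
    site_a, site_b = _resolve_sites(config, ref)
    reads = read_fastq(fastq)
    if not reads:
        raise ConfigError(f"no reads in {fastq}")

    jrs: list[JunctionRef] = []
    for kind in config.kinds:
        jrs.extend(predict_junctions(ref, site_a, site_b, kind, flank=config.flank))

    per_junction = {j.label: [] for j in jrs}
    all_alns = {
        j.label: align_reads(reads, j, config.scoring, config.identity_floor)
        for j in jrs
    }
    # assign each read to its best-scoring mapped junction
    for i in range(len(reads)):
        best_label, best_score = None, None
        for j in jrs:
            a = all_alns[j.label][i]
            if a.mapped and (best_score is None or a.score > best_score):
                best_label, best_score = j.label, a.score
        for j in jrs:
            a = all_alns[j.label][i]
            if j.label == best_label:
                per_junction[j.label].append(a)
            elif best_label is None and j is jrs[0]:
                per_junction[j.label].append(a)  # unmapped counted once

    reports = []
    mech_rows = []
    for j in jrs:
        alns = per_junction[j.label]
        if not alns:
            continue
        report = build_report(
            alns,
            j,
            sample=config.sample,
            replicate=config.replicate,
            window=config.fusion_window,
            error_rate=config.error_rate,
        )
        report = filter_observations(report, config.min_freq, config.min_var_reads)
        reports.append(report)
        write_spectrum_tsv(report, outdir / f"spectrum_{j.label}.tsv")
        if config.write_sam:
            write_sam(alns, j, outdir / f"alignments_{j.label}.sam")
        for o in report.observations:
            mechanisms = explain_indel(
                o.indel,
                j,
                ref,
                site_a,
                site_b,
                offset_range=config.offsets,
                fusion_window=config.fusion_window,
            )
            for m in mechanisms:
                if m == NHEJ_ERROR:
                    mech_rows.append((j.label, o.indel.token, o.indel.position, "nhej_error", "", "", ""))
                else:
                    mech_rows.append(
                        (
                            j.label,
                            o.indel.token,
                            o.indel.position,
                            "mechanistic",
                            m.model_a.protospacer_strand_offset,
                            m.model_b.protospacer_strand_offset,
                            m.mode.value,
                        )
                    )
    import pandas as pd

    pd.DataFrame(
        mech_rows,
        columns=["junction", "indel", "position", "class", "offset_a", "offset_b", "mode"],
    ).to_csv(outdir / "mechanisms.tsv", sep="\t", index=False)
    n_mapped = sum(r.n_mapped for r in reports)
    _write_log(
        outdir,
        config,
        {"stage": "quantify", "n_reads": len(reads), "n_mapped": n_mapped},
    )
    if n_mapped == 0:
        log.warning("zero reads mapped to any junction; reports are empty")
    return reports


def run_simulate(
    kind: str,
    scale: int,
    seed: int,
    outdir: str | Path,
    event: str = INVERSION,
    spectrum: dict[str | None, float] | None = None,
    n_reads: int = 10000,
    read_length: int = 150,
    error_rate: float = 0.001,
    flank: int = 100,
) -> Path:
    """Generate a fixture, predict its junction, and simulate reads.

    Writes the construct FASTA, a guides/primers YAML config usable by the
    quantify stage, the simulated FASTQ, and the truth table.  Returns the
    output directory.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fx = make_fixture(kind, scale=scale, seed=seed)
    write_fasta([fx.sequence], out / "construct.fasta")
    gnames = list(fx.guides)
    ga = gnames[0]
    gb = gnames[1] if len(gnames) > 1 else gnames[0]
    site_a = fx.guide_sites(ga)[0]
    if ga == gb:
        site_b = fx.guide_sites(ga)[1]
    else:
        site_b = fx.guide_sites(gb)[0]
    jrs = predict_junctions(fx.sequence, site_a, site_b, event, flank=flank)
    junction = jrs[0]
    if spectrum is None:
        spectrum = {None: 1.0}
    spec = ReadSimSpec(
        junction=junction,
        spectrum=spectrum,
        n_reads=n_reads,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed,
    )
    reads, truth = simulate_reads(spec)
    write_fastq(reads, out / "reads.fastq")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    config = {
        "reference": str(out / "construct.fasta"),
        "guide_a": ga,
        "guide_b": gb,
        "guides": {name: g.protospacer for name, g in fx.guides.items()},
        "primers": {
            name: {"forward": p.forward, "reverse": p.reverse}
            for name, p in fx.primers.items()
        },
        "kinds": [event],
        "seed": seed,
        "flank": flank,
        "outdir": str(out),
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return out
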