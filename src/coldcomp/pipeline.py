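"""End-to-end orchestration: compose -> kinetics -> group -> compare -> regress.

A run consumes a study directory (per-organism protein FASTA or CDS FASTA,
an annotation TSV, a growth-curve CSV and a Tm-weight TSV), applies every
stage, and writes diff-able TSV results plus a run manifest recording
configuration hash, input checksums and per-stage record counts.  Reruns on
identical inputs produce byte-identical result TSVs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import comparative_stats, composition_metrics, difference_regression, group_profiles
from .growth_kinetics import GrowthParameters, estimate_growth_parameters, growth_parameters_frame
from .io_model import (
    InputError,
    ProteinRecord,
    StudyConfig,
    read_annotations,
    read_growth_csv,
    read_protein_fasta,
    read_tm_table,
    translate_cds_fasta,
)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    input_checksums: dict[str, str]
    counts: dict[str, int] = field(default_factory=dict)
    seed: int | None = None
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: StudyConfig) -> str:
    from dataclasses import fields as dc_fields

    canon = json.dumps(
        {f.name: getattr(config, f.name) for f in dc_fields(config)},
        sort_keys=True,
        default=list,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class StudyInputs:
    """Resolved input paths for a run: organism -> FASTA, plus shared tables."""

    fasta: Mapping[str, Path]  # organism_id -> protein FASTA
    annotations: Path
    growth: Path
    tm_table: Path
    cds_fasta: bool = False  # if True, fasta files hold nucleotide CDSs

    @classmethod
    def from_dir(cls, directory: str | Path, cds: bool = False) -> "StudyInputs":
        d = Path(directory)
        fastas = sorted(d.glob("*.faa")) if not cds else sorted(d.glob("*.fna"))
        if not fastas:
            raise InputError(f"no {'*.fna' if cds else '*.faa'} files in {d}")
        return cls(
            {p.stem: p for p in fastas},
            d / "annotations.tsv",
            d / "growth.csv",
            d / "tm_weights.tsv",
            cds,
        )

    def validate(self) -> None:
        for name, p in [("annotations", self.annotations), ("growth", self.growth),
                        ("tm_table", self.tm_table)] + [
            (f"fasta:{o}", p) for o, p in sorted(self.fasta.items())
        ]:
            if not Path(p).exists():
                raise InputError(f"missing input {name}: {p}")


@dataclass
class PipelineResult:
    manifest: RunManifest
    growth_params: dict[str, GrowthParameters]
    matrix: difference_regression.MatrixResult
    label_slopes: list


def run_pipeline(
    inputs: StudyInputs,
    config: StudyConfig | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Execute every stage; optionally write result TSVs and the manifest."""
    config = config or StudyConfig()
    inputs.validate()
    manifest = RunManifest(
        config_hash=_config_hash(config),
        input_checksums={
            "annotations": _sha256(Path(inputs.annotations)),
            "growth": _sha256(Path(inputs.growth)),
            "tm_table": _sha256(Path(inputs.tm_table)),
            **{f"fasta:{o}": _sha256(Path(p)) for o, p in sorted(inputs.fasta.items())},
        },
        seed=seed,
        started=time.time(),
    )

    # stage: read + (optionally) translate
    proteins: list[ProteinRecord] = []
    n_dropped = 0
    for org, path in sorted(inputs.fasta.items()):
        if inputs.cds_fasta:
            recs, rejected = translate_cds_fasta(path, org, config.min_cds_nt)
            n_dropped += sum(rejected.values())
        else:
            rr = read_protein_fasta(path, org)
            recs, drop = rr.records, rr.n_dropped
            n_dropped += drop
        proteins.extend(recs)
    manifest.counts["proteins_read"] = len(proteins)
    manifest.counts["proteins_dropped"] = n_dropped

    tm_table = read_tm_table(inputs.tm_table)
    annotations = read_annotations(inputs.annotations)
    manifest.counts["annotations_read"] = len(annotations)

    # stage: compose
    profiles = composition_metrics.profile_proteome(proteins, table=tm_table)
    manifest.counts["profiles_built"] = len(profiles)

    # stage: kinetics
    curves = read_growth_csv(inputs.growth)
    manifest.counts["curves_read"] = len(curves)
    by_org: dict[str, list] = {}
    for c in curves:
        by_org.setdefault(c.organism_id, []).append(c)
    growth_params = {
        org: estimate_growth_parameters(cs, config) for org, cs in sorted(by_org.items())
    }

    # stage: group
    samples = group_profiles.build_group_samples(profiles, annotations)
    manifest.counts["samples_built"] = len(samples)
    label_tables = group_profiles.build_label_table(
        profiles, annotations, config.min_label_presence
    )
    manifest.counts["labels_retained"] = len({t.label for t in label_tables})

    # stage: compare
    pairs = comparative_stats.screen_significant_pairs(samples, config)
    manifest.counts["pairs_significant"] = len(pairs)

    # stage: regress
    strata = difference_regression.default_strata(config)
    matrix = difference_regression.run_matrix(pairs, growth_params, config, strata=strata)
    manifest.counts["regressions_fitted"] = len(matrix.results)
    manifest.counts["regressions_reported"] = len(matrix.reported())
    manifest.counts["regressions_highlighted"] = len(matrix.highlighted())

    axis_values = {o: float(g.otg_display if config.use_display_otg else g.otg)
                   for o, g in growth_params.items()}
    label_slopes = difference_regression.label_level_regression(
        label_tables, axis_values, config
    )
    manifest.counts["label_slopes"] = len(label_slopes)
    manifest.finished = time.time()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        composition_metrics.write_profiles_tsv(profiles, outdir / "profiles.tsv")
        growth_parameters_frame(growth_params.values()).to_csv(
            outdir / "growth_parameters.tsv", sep="\t", index=False, float_format="%.6g"
        )
        group_profiles.samples_frame(samples).to_csv(
            outdir / "group_samples.tsv", sep="\t", index=False, float_format="%.6g"
        )
        comparative_stats.pairs_frame(pairs).to_csv(
            outdir / "significant_pairs.tsv", sep="\t", index=False, float_format="%.6g"
        )
        difference_regression.matrix_frame(matrix).to_csv(
            outdir / "regressions.tsv", sep="\t", index=False, float_format="%.6g"
        )
        (outdir / "manifest.json").write_text(manifest.to_json())

    return PipelineResult(manifest, growth_params, matrix, label_slopes)
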