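"""Pipeline orchestration and report-table emission.

``run_pipeline`` executes the stages in order — load → composition
profiles → per-protein disorder summaries and MDP → cutoff-grid
classification → CH-CDF quadrants → group statistics → pool scores — and
writes one TSV per report surface plus a machine-readable run manifest.
Optional stages (expression pools, composition background) are skipped
with a logged notice when their inputs are absent.  Outputs are
byte-deterministic under a fixed config and seed.

Proteins present in a FASTA but missing from every track file are listed
in a ``no_track_proteins.tsv`` sidecar and excluded from disorder stages;
drops are always explicit, never silent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chcdf import BoundaryConfig, ch_cdf_point
from .composition import bootstrap_composition_test, residue_composition
from .datatypes import (
    DisorderTrack,
    ProteomeGroup,
    ValidationError,
    tracks_by_protein,
)
from .io import (
    check_track_lengths,
    read_expression_table,
    read_fasta,
    read_score_tracks,
    write_expression_table,
    write_fasta,
    write_score_tracks,
)
from .metrics import (
    CombineMode,
    DisorderSummary,
    classification_counts,
    mean_disorder_profile,
    summarize,
    summary_table,
)
from .stats import (
    chi_squared_independence,
    normalized_pool_disorder,
    one_way_anova,
    quadrant_share_table,
    tukey_hsd,
)
from .synthetic import SyntheticSpec, generate_pools, generate_proteome, generate_tracks

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from a YAML file."""

    groups: dict[str, dict[str, str]]        # name -> {"fasta": ..., "tracks": ...}
    output_dir: str
    seed: int
    background_fasta: str | None = None
    boundary_config: str | None = None
    pools: list[str] = field(default_factory=list)
    combine_mode: CombineMode = "lenient_or"
    cdf_predictor: str = "MDP"
    classification_predictor: str = "MDP"
    bootstrap_iterations: int = 10_000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValidationError("at least 2 groups required for comparative stages")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Paths of every table a run produced, plus the manifest."""

    output_dir: Path
    tables: dict[str, Path]
    manifest: dict


def _f(x: float) -> str:
    return f"{x:.6g}"


def run_pipeline(config: RunConfig) -> ReportBundle:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    boundary = (
        BoundaryConfig.from_yaml(config.boundary_config)
        if config.boundary_config
        else BoundaryConfig.default()
    )
    tables: dict[str, Path] = {}

    # ---- load -----------------------------------------------------------
    groups: dict[str, ProteomeGroup] = {}
    tracks: dict[str, list[DisorderTrack]] = {}
    for name, paths in config.groups.items():
        try:
            groups[name] = read_fasta(paths["fasta"], name=name)
            tracks[name] = read_score_tracks(paths["tracks"])
            check_track_lengths(groups[name], tracks[name])
        except (ValidationError, FileNotFoundError, KeyError) as exc:
            raise ValidationError(f"stage load [{name}]: {exc}") from exc

    # no-track sidecar: explicit drops from disorder stages
    sidecar_rows = []
    usable: dict[str, ProteomeGroup] = {}
    for name, grp in groups.items():
        tracked = {t.protein_id for t in tracks[name]}
        missing = [r.id for r in grp if r.id not in tracked]
        for pid in missing:
            sidecar_rows.append({"group": name, "protein_id": pid})
        kept = [r for r in grp if r.id in tracked]
        if not kept:
            raise ValidationError(f"stage load [{name}]: no protein has any track")
        usable[name] = ProteomeGroup(name=name, records=kept)
        if missing:
            logger.warning("group %s: %d protein(s) have no track; see sidecar",
                           name, len(missing))
    p = out / "no_track_proteins.tsv"
    pd.DataFrame(sidecar_rows, columns=["group", "protein_id"]).to_csv(
        p, sep="\t", index=False
    )
    tables["no_track_proteins"] = p

    # ---- composition profiles ------------------------------------------
    if config.background_fasta:
        background = read_fasta(config.background_fasta, name="background")
        frames = []
        for name, grp in groups.items():
            prof = bootstrap_composition_test(
                grp, background,
                iterations=config.bootstrap_iterations,
                alpha=config.alpha,
                seed=config.seed,
            )
            t = prof.table.copy()
            t.insert(0, "group", name)
            frames.append(t.reset_index())
        p = out / "composition_profiles.tsv"
        pd.concat(frames).to_csv(p, sep="\t", index=False, float_format="%.6g")
        tables["composition_profiles"] = p
    else:
        logger.info("no background proteome configured; composition stage skipped")

    # ---- per-protein summaries and MDP ---------------------------------
    summaries: dict[str, list[DisorderSummary]] = {}
    mdp_tracks: dict[str, dict[str, DisorderTrack]] = {}
    for name in usable:
        per_protein = tracks_by_protein(tracks[name])
        group_summaries = []
        mdp_tracks[name] = {}
        for pid, plist in per_protein.items():
            for t in plist:
                group_summaries.append(summarize(t))
            mdp = mean_disorder_profile(plist)
            mdp_tracks[name][pid] = mdp
            group_summaries.append(summarize(mdp))
        summaries[name] = group_summaries
    frames = []
    for name, ss in summaries.items():
        t = summary_table(ss, config.combine_mode)
        t.insert(0, "group", name)
        frames.append(t)
    all_summaries = pd.concat(frames, ignore_index=True)
    p = out / "disorder_summaries.tsv"
    all_summaries.to_csv(p, sep="\t", index=False, float_format="%.6g")
    tables["disorder_summaries"] = p

    # ---- Table-1-style predictor summary with ANOVA / Tukey ------------
    rows = []
    tukey_rows = []
    predictors = sorted(all_summaries["predictor"].unique())
    for pred in predictors:
        sub = all_summaries[all_summaries["predictor"] == pred]
        for metric in ("ads", "ppdr"):
            by_group = {
                g: sub.loc[sub["group"] == g, metric].to_numpy() for g in usable
            }
            res = one_way_anova(by_group)
            row = {"predictor": pred, "metric": metric}
            for g, vals in by_group.items():
                row[f"mean_{g}"] = vals.mean()
            row.update(
                f_statistic=res.f_statistic, p_value=res.p_value,
                df_between=res.df_between, df_within=res.df_within,
            )
            rows.append(row)
            for pair in tukey_hsd(by_group, alpha=config.alpha):
                tukey_rows.append(
                    {
                        "predictor": pred, "metric": metric,
                        "group_a": pair.group_a, "group_b": pair.group_b,
                        "mean_difference": pair.mean_difference,
                        "ci_low": pair.ci_low, "ci_high": pair.ci_high,
                        "reject_null": pair.reject_null,
                    }
                )
    p = out / "predictor_summary.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    tables["predictor_summary"] = p
    p = out / "tukey_pairs.tsv"
    pd.DataFrame(tukey_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    tables["tukey_pairs"] = p

    # ---- cutoff-grid classification ------------------------------------
    cls_pred = config.classification_predictor
    cls_summaries = {
        g: [s for s in ss if s.predictor == cls_pred] for g, ss in summaries.items()
    }
    if any(not v for v in cls_summaries.values()):
        raise ValidationError(
            f"stage classification: predictor {cls_pred!r} missing for some group"
        )
    counts = classification_counts(cls_summaries, config.combine_mode)
    p = out / "classification_counts.tsv"
    counts.to_csv(p, sep="\t", index_label="group")
    tables["classification_counts"] = p
    # empty tiers carry no information for the independence test
    cls_nonzero = counts.loc[:, counts.sum(axis=0) > 0]
    if cls_nonzero.shape[1] >= 2:
        chi = chi_squared_independence(cls_nonzero.to_numpy())
        p = out / "classification_chi2.tsv"
        with open(p, "w") as fh:
            fh.write("statistic\tdof\tp_value\n")
            fh.write(f"{_f(chi.statistic)}\t{chi.dof}\t{_f(chi.p_value)}\n")
        tables["classification_chi2"] = p
    else:
        logger.info("classification chi-squared skipped: fewer than 2 occupied tiers")

    # ---- CH-CDF ---------------------------------------------------------
    cdf_pred = config.cdf_predictor
    point_rows = []
    quad_counts = {}
    for name, grp in usable.items():
        per_protein = tracks_by_protein(tracks[name])
        qc = {q: 0 for q in ("Q1", "Q2", "Q3", "Q4")}
        for rec in grp:
            if cdf_pred == "MDP":
                track = mdp_tracks[name][rec.id]
            else:
                track = next(
                    (t for t in per_protein[rec.id] if t.predictor == cdf_pred), None
                )
                if track is None:
                    track = mdp_tracks[name][rec.id]
            pt = ch_cdf_point(rec.id, rec.sequence, track, boundary)
            qc[pt.quadrant] += 1
            point_rows.append(
                {
                    "group": name, "protein_id": pt.protein_id,
                    "delta_ch": pt.delta_ch, "delta_cdf": pt.delta_cdf,
                    "quadrant": pt.quadrant,
                }
            )
        quad_counts[name] = qc
    p = out / "chcdf_points.tsv"
    pd.DataFrame(point_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    tables["chcdf_points"] = p
    quad_df = pd.DataFrame(quad_counts).T[["Q1", "Q2", "Q3", "Q4"]]
    p = out / "quadrant_counts.tsv"
    quad_df.to_csv(p, sep="\t", index_label="group")
    tables["quadrant_counts"] = p
    nonzero = quad_df.loc[:, quad_df.sum(axis=0) > 0]
    qchi = chi_squared_independence(nonzero.to_numpy())
    p = out / "quadrant_chi2.tsv"
    with open(p, "w") as fh:
        fh.write("statistic\tdof\tp_value\n")
        fh.write(f"{_f(qchi.statistic)}\t{qchi.dof}\t{_f(qchi.p_value)}\n")
    tables["quadrant_chi2"] = p

    # ---- expression pools ----------------------------------------------
    if config.pools:
        mdp_ads = {
            pid: float(np.mean(t.scores))
            for per_group in mdp_tracks.values()
            for pid, t in per_group.items()
        }
        pool_rows = []
        for path in config.pools:
            table = read_expression_table(path)
            score = normalized_pool_disorder(table, mdp_ads)
            pool_rows.append(
                {
                    "pool_id": score.pool_id,
                    "mean_age": score.mean_age,
                    "normalized_disorder_score": score.score,
                }
            )
        p = out / "pool_scores.tsv"
        pd.DataFrame(pool_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
        tables["pool_scores"] = p
    else:
        logger.info("no expression pools configured; pool-score stage skipped")

    # ---- manifest -------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "groups": {g: len(grp) for g, grp in groups.items()},
        "predictors": predictors,
        "combine_mode": config.combine_mode,
        "tables": {k: str(v.name) for k, v in tables.items()},
    }
    mp = out / "manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return ReportBundle(output_dir=out, tables=tables, manifest=manifest)


def synthesize_corpus(spec: SyntheticSpec, output_dir: str | Path) -> dict[str, Path]:
    """Write a full synthetic corpus in the dialects the readers accept.

    Per group: a FASTA and one track TSV holding every pseudo-predictor.
    Expression pools are drawn over the ``zonules`` group when present
    (else the first group), using that group's MDP ADS values.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    groups: dict[str, ProteomeGroup] = {}
    group_tracks: dict[str, list[DisorderTrack]] = {}
    for name in spec.group_sizes:
        grp = generate_proteome(spec, name)
        groups[name] = grp
        fasta = out / f"{name}.fasta"
        write_fasta(grp, fasta)
        written[f"fasta:{name}"] = fasta
        all_tracks: list[DisorderTrack] = []
        for model in spec.predictor_models:
            all_tracks.extend(generate_tracks(grp, spec, model.name))
        group_tracks[name] = all_tracks
        tpath = out / f"{name}_tracks.tsv"
        write_score_tracks(all_tracks, tpath)
        written[f"tracks:{name}"] = tpath
    if spec.pools:
        pool_group = "zonules" if "zonules" in groups else next(iter(groups))
        mdp_ads = {
            pid: float(np.mean(mean_disorder_profile(ts).scores))
            for pid, ts in tracks_by_protein(group_tracks[pool_group]).items()
        }
        for table in generate_pools(spec, mdp_ads):
            ppath = out / f"pool_{table.pool_id}.tsv"
            write_expression_table(table, ppath)
            written[f"pool:{table.pool_id}"] = ppath
    return written
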