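"""End-to-end orchestration: simulate -> QC -> private alleles -> FST/PCA
-> GEA -> condition, with persisted intermediate artifacts and a
deterministic report.

Every stage derives its own random stream from the master seed, wall
times go to ``run.log`` only, and all report artifacts are written in a
canonical order, so re-running a configuration reproduces the report
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as skio
from .condition import condition_index, condition_table, year_allometry_test
from .config import RunConfig, child_rng
from .datatypes import SievekitError
from .differentiation import fst_permutation_test, nei_pairwise_fst, pca_genotypes
from .gea import GeaResult, cross_year_overlap, run_gea
from .private_alleles import (
    private_allele_table,
    run_private_allele_analysis,
    shared_private_alleles,
)
from .qc import apply_filters, drop_replicate_duplicates, impute_missing
from .simulate import simulate_dataset, write_dataset


class PipelineStageError(SievekitError):
    """A pipeline stage failed; the message names the stage."""


def config_hash(config: RunConfig) -> str:
    """Stable hash of the scientific configuration (paths excluded)."""
    payload = asdict(config)
    payload.pop("out_dir", None)
    payload.pop("input_dir", None)
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf8")).hexdigest()[:16]


def _child_seed(seed: int, tag: str) -> int:
    return int(child_rng(seed, tag).integers(0, 2**31 - 1))


class RunReport:
    """Handle on a finished run: artifact paths plus in-memory results."""

    def __init__(self, out_dir: Path):
        self.out_dir = Path(out_dir)
        self.artifacts: dict[str, Path] = {}
        self.results: dict[str, object] = {}

    def path(self, name: str) -> Path:
        return self.artifacts[name]


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline under one configuration."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out)
    log_lines: list[str] = []

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                res = fn()
            except SievekitError as exc:
                raise PipelineStageError(f"stage '{name}': {exc}") from exc
            log_lines.append(f"{name}: {time.perf_counter() - t0:.2f}s")
            return res

        return wrap

    # ---- data ---------------------------------------------------------
    if config.input_dir is None:
        def _simulate():
            ds = simulate_dataset(config.simulate)
            write_dataset(ds.genotypes, ds.metadata, ds.truth, out / "data")
            return ds

        ds = stage("simulate")(_simulate)
        data_dir = out / "data"
    else:
        ds = None
        data_dir = Path(config.input_dir)

    def _load():
        geno, _ = skio.read_genepop(data_dir / "genotypes.genepop")
        meta = skio.read_metadata(data_dir / "metadata.csv")
        truth_path = data_dir / "truth.json"
        truth = skio.read_truth(truth_path) if truth_path.exists() else None
        meta = (
            meta.set_index("individual_id")
            .loc[list(geno.individual_ids)]
            .reset_index()
        )
        return geno, meta, truth

    geno, meta, truth = stage("load")(_load)
    log_lines.append(f"loaded {geno.n_individuals} individuals x {geno.n_loci} loci")

    if config.label_source == "truth":
        if truth is None:
            raise PipelineStageError("stage 'labels': no truth.json for label_source=truth")
        labels_of = truth["population_labels"]
        labels = np.array([labels_of[str(i)] for i in geno.individual_ids], dtype=object)
    else:
        lab = dict(zip(meta["individual_id"], meta["population_label"]))
        labels = np.array([lab[str(i)] for i in geno.individual_ids], dtype=object)

    # ---- QC -----------------------------------------------------------
    def _qc():
        fr = apply_filters(geno, labels, config.qc)
        keep = fr.filtered
        sub_meta = (
            meta.set_index("individual_id")
            .loc[list(keep.individual_ids)]
            .reset_index()
        )
        keep2, sub_meta2, conc = drop_replicate_duplicates(keep, sub_meta)
        sub_meta2 = (
            sub_meta2.set_index("individual_id")
            .loc[list(keep2.individual_ids)]
            .reset_index()
        )
        return fr, keep2, sub_meta2, conc

    fr, gfilt, mfilt, concordance = stage("qc")(_qc)
    labels_f = np.array(
        [dict(zip(geno.individual_ids, labels))[i] for i in gfilt.individual_ids],
        dtype=object,
    )
    years_f = mfilt["year"].to_numpy()
    log_lines.append(
        f"qc retained {gfilt.n_individuals} individuals x {gfilt.n_loci} loci"
    )

    gcomplete = stage("impute")(lambda: impute_missing(gfilt))

    # ---- private alleles ---------------------------------------------
    def _private():
        return run_private_allele_analysis(
            gfilt, labels_f, years_f,
            B=config.B_private, seed=_child_seed(config.seed, "private"),
        )

    pa = stage("private_alleles")(_private)

    # ---- differentiation ---------------------------------------------
    def _fst():
        group_labels = np.array(
            [f"{y}-{l}" for y, l in zip(years_f, labels_f)], dtype=object
        )
        by_year_pop = fst_permutation_test(
            gfilt, group_labels, B=config.B_fst, seed=_child_seed(config.seed, "fst")
        )
        by_pop = nei_pairwise_fst(gfilt, labels_f)
        return by_year_pop, by_pop

    fst_year_pop, fst_pop = stage("fst")(_fst)
    pca = stage("pca")(lambda: pca_genotypes(gcomplete))

    # ---- condition ----------------------------------------------------
    def _condition():
        res = year_allometry_test(
            mfilt["length"], mfilt["weight"], mfilt["year"]
        )
        return res

    cond = stage("condition")(_condition)

    # ---- GEA per year -------------------------------------------------
    def _gea():
        env = mfilt.copy()
        env["condition_index"] = cond.index
        out_by_year: dict[int, GeaResult] = {}
        for year in sorted(pd.unique(years_f)):
            rows = np.where(years_f == year)[0]
            out_by_year[int(year)] = run_gea(
                gcomplete.take_individuals(rows), env.iloc[rows], config.gea
            )
        years = sorted(out_by_year)
        shared, per_var = cross_year_overlap(
            out_by_year[years[0]].candidates, out_by_year[years[1]].candidates
        ) if len(years) == 2 else (set(), {})
        return out_by_year, shared, per_var

    gea_by_year, gea_shared, gea_per_var = stage("gea")(_gea)

    # ---- report -------------------------------------------------------
    def _report():
        _write_report(
            report, config, fr, concordance, pa, fst_year_pop, fst_pop,
            pca, gea_by_year, gea_shared, cond, mfilt,
        )

    stage("report")(_report)

    report.results.update(
        {
            "filter": fr,
            "private_alleles": pa,
            "fst_year_pop": fst_year_pop,
            "fst_pop": fst_pop,
            "pca": pca,
            "gea_by_year": gea_by_year,
            "gea_shared": gea_shared,
            "condition": cond,
            "metadata": mfilt,
            "genotypes": gfilt,
            "truth": truth,
        }
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report


def _write_report(
    report, config, fr, concordance, pa, fst_year_pop, fst_pop, pca,
    gea_by_year, gea_shared, cond, meta,
):
    out = report.out_dir
    art = report.artifacts

    art["filter_log"] = out / "filter_log.tsv"
    fr.log.to_csv(art["filter_log"], sep="\t", index=False)

    art["replicate_concordance"] = out / "replicate_concordance.tsv"
    concordance.to_csv(art["replicate_concordance"], sep="\t", index=False)

    art["table1_fst"] = out / "table1_fst.tsv"
    fst_year_pop.table().to_csv(art["table1_fst"], sep="\t")

    art["fst_populations"] = out / "fst_populations.tsv"
    fst_pop.fst.round(6).to_csv(art["fst_populations"], sep="\t")

    art["table2_private_alleles"] = out / "table2_private_alleles.tsv"
    private_allele_table(pa).to_csv(art["table2_private_alleles"], sep="\t", index=False)

    art["table3_shared_private"] = out / "table3_shared_private.tsv"
    shared = pa.shared_matrix if pa.shared_matrix is not None else shared_private_alleles(pa)
    shared.to_csv(art["table3_shared_private"], sep="\t")

    art["table4_gea_counts"] = out / "table4_gea_counts.tsv"
    counts = pd.DataFrame(
        {str(y): r.candidate_counts() for y, r in sorted(gea_by_year.items())}
    )
    counts.index.name = "variable"
    counts.to_csv(art["table4_gea_counts"], sep="\t")

    art["gea_overlap"] = out / "gea_overlap.txt"
    art["gea_overlap"].write_text("\n".join(sorted(map(str, gea_shared))) + "\n")

    art["pca_scores"] = out / "pca_scores.csv"
    k = min(10, pca.scores.shape[1])
    pd.DataFrame(
        pca.scores[:, :k], columns=[f"PC{i + 1}" for i in range(k)]
    ).assign(individual_id=meta["individual_id"].to_numpy()).to_csv(
        art["pca_scores"], index=False
    )

    art["figure5_allometry"] = out / "figure5_allometry.json"
    interaction = {
        row["term"]: {
            "estimate": round(float(row["estimate"]), 10),
            "p": round(float(row["p"]), 10),
        }
        for _, row in cond.interaction_fit.iterrows()
    }
    with open(art["figure5_allometry"], "w") as fh:
        json.dump(
            {
                "pooled_fit": {k2: round(float(v), 10) for k2, v in cond.pooled_fit.items()},
                "interaction_fit": interaction,
                "year_levels": [int(y) for y in cond.year_levels],
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    art["condition_index"] = out / "condition_index.csv"
    condition_table(cond, meta).to_csv(art["condition_index"], index=False)

    art["report"] = out / "report.json"
    summary = {
        "provenance": {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "package": "sievekit",
            "version": __import__("sievekit").__version__,
        },
        "n_individuals": int(len(meta)),
        "n_loci": int(len(pca.kept_loci) + len(pca.dropped_loci)),
        "fst_populations_mean": round(
            float(np.nanmean(fst_pop.fst.to_numpy())), 8
        ),
        "gea_candidates": {
            str(y): {v: sorted(map(str, r.candidates[v])) for v in r.variables}
            for y, r in sorted(gea_by_year.items())
        },
        "gea_lambda": {
            str(y): {v: round(float(r.lam[v]), 8) for v in r.variables}
            for y, r in sorted(gea_by_year.items())
        },
        "gea_shared_across_years": sorted(map(str, gea_shared)),
        "private_allele_p": {
            str(p): [round(float(x), 8) for x in pv] for p, pv in sorted(pa.p_values.items())
        },
        "tables": {k2: str(v.name) for k2, v in sorted(art.items()) if k2 != "report"},
    }
    with open(art["report"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
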