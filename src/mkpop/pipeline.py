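"""End-to-end orchestration: read -> filter -> per-locus statistics ->
MK tables -> single-locus tests + FDR -> exclusions -> multilocus fits ->
model comparison -> bootstrap/permutation, with deterministic TSV/JSON
reports.

Two input modes exist: ``alignments`` (per-locus FASTA + manifest, the
full sequence pipeline) and ``counts`` (a pre-tabulated count TSV such as
the bundled dataset, which drives the test and multilocus stages only).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import datasets
from .align_io import (
    count_haplotypes,
    filter_low_frequency_variants,
    read_locus_alignment,
    read_manifest,
)
from .mk_counts import build_mk_table, pool_polymorphism
from .mk_multilocus import (
    LocusRecord,
    adaptive_rate_a,
    alpha_summary,
    compare_models,
    fit_model,
    per_locus_alpha,
)
from .mk_single import attach_fdr, mk_test
from .popgen import DEFAULT_SEED, count_sites, locus_summary


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and locus."""


@dataclass
class RunConfig:
    mode: str = "counts"  # "counts" | "alignments"
    counts_path: str | None = None  # None -> bundled dataset
    alignments_dir: str | None = None
    manifest_path: str | None = None
    ingroup_species: str = "D_pulex"
    filter_threshold: float = 0.10
    pooling: str = "pooled"  # single-locus test pooling
    min_expected: float = 2.0
    models: tuple[str, ...] = ("M0", "M1", "M2", "M3")
    polymorphism: str = "ingroup"  # multilocus polymorphism mode
    sample_size_weights: bool = False  # published-analysis convention
    coalescent_reps: int = 10000
    bootstrap_reps: int = 1000
    permutation_reps: int = 1000
    seed: int = DEFAULT_SEED
    outdir: str = "mkpop_out"
    ln_fraction: float = datasets.DEFAULT_LN_FRACTION

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (everything except
        where the reports are written)."""
        d = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _fmt(df: pd.DataFrame, spec: dict[str, int]) -> pd.DataFrame:
    """Fixed-precision string formatting for deterministic TSV output."""
    out = df.copy()
    for col, dp in spec.items():
        if col in out.columns:
            out[col] = [
                "NA" if (isinstance(v, float) and math.isnan(v)) else f"{v:.{dp}f}"
                for v in out[col]
            ]
    return out


def _write(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _records_from_alignments(config: RunConfig):
    manifest = read_manifest(config.manifest_path)
    aln_dir = Path(config.alignments_dir)
    records, stats_rows = [], []
    for entry in manifest.to_dict("records"):
        locus = entry["locus_id"]
        try:
            aln = read_locus_alignment(
                aln_dir / f"{locus}.fasta", entry, config.ingroup_species
            )
            aln = filter_low_frequency_variants(aln, config.filter_threshold)
            summary, taj = locus_summary(
                aln, coalescent_reps=config.coalescent_reps, seed=config.seed
            )
            sites = count_sites(aln)
            mk = build_mk_table(aln)
            h_in, h_out = count_haplotypes(aln)
        except Exception as exc:  # noqa: BLE001 - structured re-raise
            raise PipelineError(f"locus {locus!r}, stage sequence-stats: {exc}") from exc
        stats_rows.append(
            dict(
                locus=locus, gene_class=entry["class"],
                n_in=len(aln.ingroup_haplotypes), n_out=len(aln.outgroup_haplotypes),
                alleles_in=h_in, alleles_out=h_out,
                pi_s=summary.pi_s, pi_a=summary.pi_a,
                K_s=summary.K_s, K_a=summary.K_a, ka_ks=summary.ka_ks,
                D=taj.D, D_p=taj.p,
            )
        )
        records.append(
            LocusRecord(
                locus_id=locus, gene_class=entry["class"], mk=mk,
                L_s=sites.L_s, L_n=sites.L_n,
                n_in=len(aln.ingroup_haplotypes),
                n_out=len(aln.outgroup_haplotypes),
                include_multilocus=bool(entry["include_multilocus"]),
            )
        )
    return records, pd.DataFrame(stats_rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns {name: DataFrame} and writes TSV/JSON
    reports plus the full config (with seeds) to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    stats_df = None
    if config.mode == "alignments":
        records, stats_df = _records_from_alignments(config)
    elif config.mode == "counts":
        if config.counts_path is None:
            df = datasets.load_locus_counts()
        else:
            df = pd.read_csv(config.counts_path, sep="\t", comment="#")
        records = datasets.records_from_counts(df, ln_fraction=config.ln_fraction)
    else:
        raise PipelineError(f"stage config: unknown mode {config.mode!r}")

    # single-locus MK tests + FDR
    results = [
        mk_test(r.mk, pooling=config.pooling, min_expected=config.min_expected)
        for r in records
    ]
    results = attach_fdr(results)
    mk_rows = []
    for r, t in zip(records, results):
        mk_rows.append(
            dict(
                locus=r.locus_id, gene_class=r.gene_class,
                Pn_in=r.mk.pn_in, Ps_in=r.mk.ps_in,
                Pn_out=r.mk.pn_out, Ps_out=r.mk.ps_out,
                Dn=r.mk.dn, Ds=r.mk.ds,
                G=t.G, p=t.p, q=t.q, method=t.method,
            )
        )
    mk_df = pd.DataFrame(mk_rows)

    # multilocus stage on the included loci
    included = [r for r in records if r.include_multilocus]
    try:
        fits = [
            fit_model(
                included, m, seed=config.seed,
                polymorphism=config.polymorphism,
                sample_size_weights=config.sample_size_weights,
            )
            for m in config.models
        ]
        models_df = compare_models(fits)
        summary = alpha_summary(
            included,
            bootstrap_reps=config.bootstrap_reps,
            permutation_reps=config.permutation_reps,
            seed=config.seed,
            polymorphism=config.polymorphism,
            sample_size_weights=config.sample_size_weights,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage multilocus: {exc}") from exc

    alpha_rows = []
    for r in included:
        a_i = per_locus_alpha(r.mk)
        alpha_rows.append(
            dict(
                locus=r.locus_id, gene_class=r.gene_class,
                alpha=a_i,
                a=adaptive_rate_a(a_i, r.mk.Dn, r.L_n)
                if not math.isnan(a_i) else float("nan"),
            )
        )
    alpha_df = pd.DataFrame(alpha_rows).sort_values(
        "a", ascending=False, kind="mergesort"
    ).reset_index(drop=True)

    class_rows = [
        dict(gene_class=c, alpha=pt, ci_lo=lo, ci_hi=hi,
             permutation_p=summary.permutation_p)
        for c, (pt, lo, hi) in summary.alpha_by_class.items()
    ]
    class_df = pd.DataFrame(class_rows)

    # reports (fixed precision: 4 dp for rates/pi/K, 3 dp for G/D)
    if stats_df is not None:
        _write(
            _fmt(stats_df, dict(pi_s=4, pi_a=4, K_s=4, K_a=4, ka_ks=4, D=3, D_p=4)),
            outdir / "locus_stats.tsv", cfg_hash,
        )
    _write(_fmt(mk_df, dict(G=3, p=4, q=4)), outdir / "mk_tests.tsv", cfg_hash)
    _write(
        _fmt(models_df, dict(lnL=1, D=2, p=4, AICc=1, delta_i=1, w_i=4)),
        outdir / "model_comparison.tsv", cfg_hash,
    )
    _write(_fmt(alpha_df, dict(alpha=5, a=5)), outdir / "per_locus_alpha.tsv", cfg_hash)
    _write(
        _fmt(class_df, dict(alpha=3, ci_lo=3, ci_hi=3, permutation_p=4)),
        outdir / "class_alpha.tsv", cfg_hash,
    )
    with open(outdir / "run.json", "w") as fh:
        json.dump(
            dict(config=asdict(config), config_hash=cfg_hash), fh,
            indent=2, default=str,
        )

    out = dict(
        mk_tests=mk_df, model_comparison=models_df,
        per_locus_alpha=alpha_df, class_alpha=class_df,
    )
    if stats_df is not None:
        out["locus_stats"] = stats_df
    return out
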