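"""Assemble a full study-style report from the analysis modules.

The report bundles, per population scope (whole pedigree, reference set,
and each lineage within the reference set): completeness summaries,
inbreeding and relatedness means, the proportion of inbred animals, the
gene-origin summary with the diversity-loss partition, effective population
sizes, generation intervals, and — when a partition is given — Wright's
F-statistics, plus yearly trend series of mean F and births.  Every number
is a pure function of (pedigree, reference, partition, config, seed) and is
tagged with the module that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestral, completeness, demography, fstats, gene_origin
from . import inbreeding as inb
from .pedigree_io import Pedigree, PedigreeError, ReferenceSet

__all__ = ["summary_report", "write_report"]


def _pct(x: float) -> float:
    """Fractions rendered as two-decimal percentages."""
    return float(round(100.0 * x, 2))


def _mean_sd(v: np.ndarray) -> dict:
    v = np.asarray(v, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {"n": 0, "mean": float("nan"), "sd": float("nan")}
    return {"n": int(v.size), "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0}


def _scope_stats(ped: Pedigree, mask: np.ndarray, F, ar, comp) -> dict:
    Fm = F[mask]
    return {
        "n_animals": int(mask.sum()),
        "completeness": {
            "module": "completeness",
            "max_gen": _mean_sd(comp["max_gen"].to_numpy()[mask]),
            "full_gen": _mean_sd(comp["full_gen"].to_numpy()[mask]),
            "cge": _mean_sd(comp["cge"].to_numpy()[mask]),
            "pci": _mean_sd(comp["pci"].to_numpy()[mask]),
        },
        "inbreeding": {
            "module": "inbreeding",
            "F_pct": {k: (_pct(v) if k != "n" else v)
                      for k, v in _mean_sd(Fm).items()},
            "AR_pct": {k: (_pct(v) if k != "n" else v)
                       for k, v in _mean_sd(ar[mask]).items()},
            "proportion_inbred_pct": _pct(float((Fm > 0).mean()))
            if Fm.size else float("nan"),
        },
    }


def summary_report(ped: Pedigree, ref: ReferenceSet,
                   partition: dict | str | None = None,
                   *, pci_depth: int = 5, genedrop_replicates: int = 0,
                   genedrop_seed: int | None = None) -> dict:
    """Compute the full report as a JSON-serialisable dict.

    ``partition`` may be a mapping id -> label or the string name of a
    pedigree column (e.g. ``"lineage"``).  Gene dropping is only run when
    ``genedrop_replicates`` > 0 (it needs an explicit seed).
    """
    ped.require_ordered()
    comp = completeness.completeness_table(ped, depth=pci_depth)
    F = inb.inbreeding_meuwissen_luo(ped)
    ar = inb.average_relatedness(ped, F)
    ref_ids = list(ref.ids)
    mask_ref = np.zeros(len(ped), dtype=bool)
    for a in ref_ids:
        mask_ref[ped.index_of(a)] = True

    if isinstance(partition, str):
        col = ped.df[partition]
        partition = {a: col.iloc[ped.index_of(a)] for a in ref_ids
                     if not pd.isna(col.iloc[ped.index_of(a)])}

    report: dict = {"scopes": {}, "modules": {}}
    report["scopes"]["total"] = _scope_stats(
        ped, np.ones(len(ped), dtype=bool), F, ar, comp)
    report["scopes"]["reference"] = _scope_stats(ped, mask_ref, F, ar, comp)
    if partition:
        for label in sorted({str(v) for v in partition.values()}):
            m = np.zeros(len(ped), dtype=bool)
            for a, v in partition.items():
                if str(v) == label:
                    m[ped.index_of(a)] = True
            report["scopes"][f"lineage:{label}"] = _scope_stats(
                ped, m, F, ar, comp)

    origin = gene_origin.gene_origin_summary(ped, ref)
    report["modules"]["gene_origin"] = {
        "fe": origin.fe, "fa": origin.fa, "fa_over_fe": origin.fa / origin.fe,
        "fge": origin.fge, "n50": origin.n50,
        "mean_coancestry": origin.mean_coancestry,
        "loss_total_pct": _pct(origin.loss_total),
        "loss_founder_pct": _pct(origin.loss_founder),
        "loss_drift_pct": _pct(origin.loss_drift),
        "n_founders_true": origin.n_founders_true,
        "n_founders_phantom": origin.n_founders_phantom,
        "top_founders": sorted(origin.contributions.items(),
                               key=lambda kv: -kv[1])[:20],
        "top_ancestors": origin.ancestors[:20],
    }

    cge = comp["cge"].to_numpy()
    mg = comp["max_gen"].to_numpy()
    try:
        ne = inb.ne_estimates(F, cge, mg, mask_ref)
        report["modules"]["ne"] = {
            k: {"ne": v.ne, "b": v.b, "mean_delta_F": v.mean_delta_F,
                "dispersion": v.dispersion, "n": v.n}
            for k, v in ne.items()
        }
    except PedigreeError as err:  # too few informative animals
        report["modules"]["ne"] = {"undefined": str(err)}

    report["modules"]["demography"] = {
        "generation_intervals": demography.generation_intervals(ped)
        .paths,
        "age_at_any_offspring": demography.generation_intervals(
            ped, "age-at-any-offspring").paths,
        "reproduction": demography.reproductive_summary(ped),
    }

    if partition and len({str(v) for v in partition.values()}) >= 1:
        fs = fstats.wright_f_statistics(ped, ref, partition)
        report["modules"]["fstats"] = {
            "fis": fs.fis, "fst": fs.fst, "fit": fs.fit,
            "f_S": fs.f_S, "f_T": fs.f_T, "F_bar": fs.F_bar,
        }

    if genedrop_replicates > 0:
        gd = ancestral.gene_drop(ped, genedrop_replicates, genedrop_seed)
        m = mask_ref
        report["modules"]["ancestral"] = {
            "mean_F_hat": float(gd.F_hat[m].mean()),
            "mean_Fa_kal": float(gd.Fa_kal[m].mean()),
            "mean_F_new": float(gd.F_new[m].mean()),
            "mean_Fa_ballou": float(gd.Fa_ballou[m].mean()),
            "replicates": gd.replicates, "seed": gd.seed,
        }

    # yearly trend: mean F and number of births per birth year
    years = ped.df["birth_date"].dt.year
    trend = pd.DataFrame({"year": years, "F": F}).dropna()
    by = trend.groupby("year")["F"]
    report["trend"] = {
        "year": [int(y) for y in by.mean().index],
        "mean_F_pct": [_pct(v) for v in by.mean().to_numpy()],
        "births": [int(v) for v in by.size().to_numpy()],
    }

    # per-generation analogue table (by max_gen class)
    gen_tab = pd.DataFrame({"max_gen": mg, "F": F, "AR": ar})
    g = gen_tab.groupby("max_gen")
    report["per_generation"] = {
        "max_gen": [int(v) for v in g.size().index],
        "n": [int(v) for v in g.size()],
        "mean_F_pct": [_pct(v) for v in g["F"].mean()],
        "mean_AR_pct": [_pct(v) for v in g["AR"].mean()],
    }
    return report


def write_report(report: dict, outdir) -> None:
    """Write the JSON summary plus TSV tables under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    pd.DataFrame(report["per_generation"]).to_csv(
        out / "per_generation.tsv", sep="\t", index=False)
    pd.DataFrame(report["trend"]).to_csv(
        out / "trend.tsv", sep="\t", index=False)
    og = report["modules"]["gene_origin"]
    pd.DataFrame(og["top_founders"], columns=["id", "contribution"]).to_csv(
        out / "founder_contributions.tsv", sep="\t", index=False)
    pd.DataFrame(og["top_ancestors"], columns=["id", "marginal"]).to_csv(
        out / "ancestor_contributions.tsv", sep="\t", index=False)
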