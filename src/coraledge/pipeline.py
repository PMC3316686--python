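"""End-to-end study orchestration.

Runs the whole analysis from one configuration and one seed: generate or
load inputs, randomly resolve supertree polytomies, score and rank species
by EDGE, test phylogenetic signal of extinction probability (Blomberg's K)
and of binary threat traits (Fritz & Purvis' D), correlate traits with
independent contrasts, compare PD loss under threat-based and top-ranked
extinction scenarios to random pruning, and test tree imbalance against
the Yule model. Every stage writes a delimited table; a machine-readable
``summary.json`` echoes the configuration and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, edge, signal, synth
from .edge import EdgeScore, PETransform, RedListCategory, THREATENED
from .signal import TraitVector
from .tree import PhyloTree, read_newick, resolve_polytomies

__all__ = [
    "RunConfig",
    "run_study",
    "category_proportions",
    "read_species_table",
    "read_traits_table",
    "DEFAULT_CONTRAST_PAIRS",
]

#: Trait pairs tested for correlated evolution with independent contrasts.
DEFAULT_CONTRAST_PAIRS = (
    ("bleaching_susceptible", "disease_susceptible"),
    ("bleaching_susceptible", "cots_predation_susceptible"),
    ("bleaching_susceptible", "bleaching_resistant"),
    ("disease_susceptible", "disease_resistant"),
    ("disease_susceptible", "quick_recovery"),
)


@dataclass
class RunConfig:
    outdir: str = "coraledge_run"
    seed: int = 0
    # either a synthetic study...
    synthetic: synth.SyntheticStudyConfig | None = None
    # ...or explicit input files
    tree_path: str | None = None
    species_table_path: str | None = None
    traits_path: str | None = None
    n_resolutions: int = 1000
    resolution_method: str = "sequential"
    n_null: int = 1000
    n_signal_resolutions: int = 100
    n_signal_null: int = 1000
    pe_transform: str = "IUCN100"
    top_k: int = 30
    contrast_pairs: tuple = DEFAULT_CONTRAST_PAIRS


# ----------------------------------------------------------------------
# table I/O
# ----------------------------------------------------------------------

def read_species_table(path) -> pd.DataFrame:
    """Read a species table (TSV: species, category, optional abundance and
    n_source_trees columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    if "species" not in df.columns or "category" not in df.columns:
        raise ValueError("species table needs 'species' and 'category' columns")
    df["category"] = df["category"].map(RedListCategory.coerce)
    return df


def read_traits_table(path) -> dict:
    """Read a traits table (TSV: species + one 0/1 or numeric column per
    trait) into TraitVector objects."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str}).set_index("species")
    traits = {}
    for col in df.columns:
        vals = df[col].astype(float)
        kind = "binary" if set(vals.unique()) <= {0.0, 1.0} else "continuous"
        traits[col] = TraitVector(
            values=vals.to_dict(), trait_name=col, kind=kind
        )
    return traits


# ----------------------------------------------------------------------
# category proportions
# ----------------------------------------------------------------------

def category_proportions(
    categories: dict,
    thresholds=("EN_and_above", "VU_and_above", "NT_and_above"),
) -> dict:
    """Proportion of species at or above each threat threshold.

    Threshold proportions use *all* species (including Data Deficient) as
    the denominator, rounded to 3 decimals. The threatened percentage
    (CR+EN+VU) uses only assessed species — DD and NE excluded — rounded
    to 1 decimal. Both conventions are reported with their denominators.
    """
    if not categories:
        raise ValueError("empty category map")
    cats = [RedListCategory.coerce(c) for c in categories.values()]
    n_total = len(cats)
    out = {"n_total": n_total, "proportions": {}}
    for name in thresholds:
        members = diversity.SCENARIOS[name]
        k = sum(1 for c in cats if c in members)
        out["proportions"][name] = round(k / n_total, 3)
    assessed = [
        c for c in cats if c not in (RedListCategory.DD, RedListCategory.NE)
    ]
    n_threatened = sum(1 for c in assessed if c in THREATENED)
    out["n_assessed"] = len(assessed)
    out["threatened_pct_of_assessed"] = (
        round(100.0 * n_threatened / len(assessed), 1) if assessed else float("nan")
    )
    return out


# ----------------------------------------------------------------------
# study stages
# ----------------------------------------------------------------------

def _load_inputs(config: RunConfig, outdir: Path, resume: bool):
    indir = outdir / "inputs"
    if config.synthetic is not None:
        if resume and (indir / "supertree.nwk").exists():
            tree = read_newick(indir / "supertree.nwk")
            df = read_species_table(indir / "species_table.tsv")
            traits = read_traits_table(indir / "traits.tsv")
        else:
            study = synth.simulate_study(config.synthetic)
            synth.write_study(study, indir)
            tree = study.tree
            traits = study.traits
            df = read_species_table(indir / "species_table.tsv")
        categories = dict(zip(df["species"], df["category"]))
        return tree, categories, traits, df
    for name, p in (
        ("tree", config.tree_path),
        ("species table", config.species_table_path),
    ):
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"missing input: {name} ({p})")
    tree = read_newick(config.tree_path)
    df = read_species_table(config.species_table_path)
    categories = dict(zip(df["species"], df["category"]))
    traits = (
        read_traits_table(config.traits_path)
        if config.traits_path and Path(config.traits_path).exists()
        else {}
    )
    return tree, categories, traits, df


def _edge_table(scores: list[EdgeScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": s.species,
                "ed_mean": s.ed_mean,
                "ed_sd": s.ed_sd,
                "pe": s.pe,
                "edge_mean": s.edge_mean,
                "edge_sd": s.edge_sd,
                "rank": s.rank,
            }
            for s in sorted(scores, key=lambda s: s.rank)
        ]
    )


def _threat_indicator(categories: dict, scenario: str, tips) -> TraitVector:
    members = diversity.SCENARIOS[scenario]
    return TraitVector(
        values={
            t: 1.0 if RedListCategory.coerce(categories[t]) in members else 0.0
            for t in tips
        },
        trait_name=scenario,
        kind="binary",
    )


def _signal_tables(
    resolutions, categories, traits, transform, config: RunConfig
):
    """Mean +/- SD of K (for PE) and of D (per binary trait) over random
    resolutions, with mean p-values."""
    reps = resolutions.replicates[: config.n_signal_resolutions]
    tips = resolutions.base.leaf_labels()
    pe_trait = TraitVector(
        values={
            t: edge.pe_from_category(categories[t], transform, strict_ne=False)
            for t in tips
        },
        trait_name="extinction_probability",
        kind="continuous",
    )
    k_vals, k_ps = [], []
    for i, rep in enumerate(reps):
        res = signal.k_randomization_test(
            rep, pe_trait, n_permutations=config.n_signal_null, seed=_derive(config.seed, 10, i)
        )
        k_vals.append(res.observed)
        k_ps.append(res.p_vs_random)
    k_row = {
        "trait": "extinction_probability",
        "statistic": "K",
        "mean": float(np.mean(k_vals)),
        "sd": float(np.std(k_vals, ddof=1)) if len(k_vals) > 1 else 0.0,
        "p_vs_random": float(np.mean(k_ps)),
    }

    binary_traits = dict(traits)
    for scen in ("EN_and_above", "VU_and_above", "NT_and_above"):
        binary_traits = {scen: _threat_indicator(categories, scen, tips), **binary_traits}
    d_rows = []
    for name, trait in binary_traits.items():
        if trait.kind != "binary":
            continue
        vec = trait.vector(tips)
        if vec.sum() in (0, len(vec)):
            warnings.warn(f"trait {name!r} is monomorphic; skipped")
            continue
        d_vals, p0s, p1s = [], [], []
        for i, rep in enumerate(reps):
            res = signal.fritz_purvis_d(
                rep,
                trait,
                n_permutations=config.n_signal_null,
                n_brownian=config.n_signal_null,
                seed=_derive(config.seed, 11, i),
            )
            d_vals.append(res.observed)
            p0s.append(res.p_vs_clumped)
            p1s.append(res.p_vs_random)
        d_rows.append(
            {
                "trait": name,
                "proportion_of_species": round(float(vec.mean()), 3),
                "D_mean": float(np.mean(d_vals)),
                "D_sd": float(np.std(d_vals, ddof=1)) if len(d_vals) > 1 else 0.0,
                "p_D_is_0": float(np.mean(p0s)),
                "p_D_is_1": float(np.mean(p1s)),
            }
        )
    return k_row, pd.DataFrame(d_rows)


def _contrast_table(tree: PhyloTree, traits: dict, pairs) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        if a not in traits or b not in traits:
            continue
        res = signal.binary_contrast_correlation(tree, traits[a], traits[b])
        rows.append(
            {
                "trait_x": a,
                "trait_y": b,
                "slope": res.slope,
                "correlation": res.correlation,
                "t": res.t_statistic,
                "p_value": res.p_value,
                "n_contrasts": res.n_contrasts,
            }
        )
    return pd.DataFrame(rows)


def _derive(seed: int, *path: int) -> int:
    """Deterministic child seed below 2^31."""
    ss = np.random.SeedSequence([int(seed), *[int(p) for p in path]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def run_study(config: RunConfig, resume: bool = False) -> dict:
    """Run the full study; returns the summary dict (also written to
    ``summary.json`` in the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        tree, categories, traits, species_df = _load_inputs(config, outdir, resume)
        missing = [t for t in tree.leaf_labels() if t not in categories]
        if missing:
            raise ValueError(
                f"species table lacks categories for {len(missing)} tips, "
                f"e.g. {sorted(missing)[:3]}"
            )
        transform = PETransform.named(config.pe_transform)

        stage = "polytomy resolution"
        resolutions = resolve_polytomies(
            tree,
            config.n_resolutions,
            seed=_derive(config.seed, 1),
            method=config.resolution_method,
        )

        stage = "EDGE scoring"
        scores = edge.edge_scores(
            resolutions, categories, transform, strict_ne=False
        )
        edge_df = _edge_table(scores)
        edge_df.to_csv(outdir / "edge_ranking.tsv", sep="\t", index=False)

        stage = "category proportions"
        props = category_proportions(categories)

        stage = "signal tests"
        k_row, d_df = _signal_tables(
            resolutions, categories, traits, transform, config
        )
        d_df.to_csv(outdir / "signal_table.tsv", sep="\t", index=False)

        stage = "independent contrasts"
        contrast_df = _contrast_table(resolutions.replicates[0], traits, config.contrast_pairs)
        contrast_df.to_csv(outdir / "contrasts.tsv", sep="\t", index=False)

        stage = "PD loss"
        pd_rows = []
        for i, scen in enumerate(("EN_and_above", "VU_and_above", "NT_and_above")):
            res = diversity.extinction_scenario_test(
                tree,
                categories,
                scenario=scen,
                n_null=config.n_null,
                seed=_derive(config.seed, 20, i),
            )
            pd_rows.append(res)
        top = diversity.top_k_loss_test(
            tree,
            scores,
            k=min(config.top_k, tree.n_leaves - 1),
            n_null=config.n_null,
            seed=_derive(config.seed, 21),
        )
        pd_rows.append(top)
        pd_df = pd.DataFrame(
            [
                {
                    "scenario": r.scenario_name,
                    "n_removed": r.n_removed,
                    "pd_observed": r.pd_observed,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "t": r.t_statistic,
                    "p_value": r.p_value,
                    "p_greater_loss": r.p_greater_loss,
                    "p_smaller_loss": r.p_smaller_loss,
                    "p_rank": r.p_rank,
                    "direction": r.direction,
                }
                for r in pd_rows
            ]
        )
        pd_df.to_csv(outdir / "pd_loss.tsv", sep="\t", index=False)

        stage = "imbalance"
        imb = diversity.yule_imbalance_test(
            resolutions.replicates[0],
            n_simulations=config.n_null,
            seed=_derive(config.seed, 30),
        )
    except Exception as exc:
        raise RuntimeError(f"study failed at stage: {stage}") from exc

    summary = {
        "config": _jsonable(config),
        "seed": config.seed,
        "n_species": tree.n_leaves,
        "category_proportions": props,
        "edge": {
            "top_species": edge_df.head(min(10, len(edge_df)))["species"].tolist(),
            "ed_total_mean": float(edge_df["ed_mean"].sum()),
        },
        "signal": {
            "K_extinction_probability": k_row,
            "D_table": d_df.to_dict(orient="records"),
            "contrasts": contrast_df.to_dict(orient="records"),
        },
        "pd_loss": pd_df.to_dict(orient="records"),
        "imbalance": {
            "colless_observed": imb.colless_observed,
            "null_mean": float(imb.null_colless.mean()),
            "p_value": imb.p_value,
        },
        "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(getattr(k, "value", k)): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, RedListCategory):
        return obj.value
    return obj
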