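"""End-to-end orchestration: networks -> associations -> regression ->
selection -> enrichment -> consensus, with deterministic seeding and a
manifest.

A run is a pure function of (inputs, config, seed): rerunning the same
config reproduces byte-identical stage outputs. Inputs come either from
files (interactome/drug-target/phenotype/GMT/screen tables) or from the
synthetic generator when the config carries a scenario.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import consensus as cns
from . import enrichment as enr
from . import io_formats as io
from . import pathfx as pfx
from . import regression as reg
from . import synthetic as syn

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    name: str
    path: str | None = None  # None when synthetic
    outcome_type: str = "continuous"
    favorable_sign: int = 1
    model_kind: str = "linear_ridge"
    alpha: float = 1.0
    split_fraction: float = 0.7
    selection_mode: str = "threshold"
    favorable_bound: float | None = None
    unfavorable_bound: float | None = None
    top_k: int | None = None
    fraction: float | None = None

    def selection_rule(self) -> reg.SelectionRule:
        return reg.SelectionRule(
            mode=self.selection_mode,
            favorable_bound=self.favorable_bound,
            unfavorable_bound=self.unfavorable_bound,
            k=self.top_k,
            fraction=self.fraction,
        )


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    interactome: str | None = None
    drug_targets: str | None = None
    phenotypes: str | None = None
    gene_sets: str | None = None
    screens: list[ScreenConfig] = field(default_factory=list)
    synthetic: dict | None = None  # SyntheticScenario kwargs; replaces file inputs
    max_depth: int = 2
    null_iters: int = 100
    pathfx_alpha: float = 0.05
    n_shuffles: int = 100
    enrich_top_k: int = 10
    enrich_alpha: float = 0.05
    write_network_files: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        screens = [ScreenConfig(**s) for s in raw.pop("screens", [])]
        return cls(screens=screens, **raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_selection(
    scn: ScreenConfig, scenario: syn.SyntheticScenario, kind: str
) -> ScreenConfig:
    """Fill threshold bounds from the scenario's selection bound when unset."""
    if scn.selection_mode != "threshold" or scn.favorable_bound is not None:
        return scn
    b = scenario.screen_selection_bound(kind)
    if scn.favorable_sign == 1:
        return dataclasses.replace(scn, favorable_bound=b, unfavorable_bound=-b)
    return dataclasses.replace(scn, favorable_bound=-b, unfavorable_bound=b)


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        scenario = syn.SyntheticScenario(seed=config.seed, **config.synthetic)
        layout = {
            s.name: (
                "odds_ratio" if s.name == "clinical" else ("binary" if s.outcome_type == "binary" else "continuous"),
                s.favorable_sign,
            )
            for s in config.screens
        } or None
        ds = syn.generate_dataset(scenario, screens=layout)
        kinds = {n: k for n, (k, _) in (layout or syn.THREE_SCREENS).items()}
        screen_cfgs = config.screens or [
            ScreenConfig(name=n, favorable_sign=ds.truth.favorable_sign[n]) for n in sorted(ds.screens)
        ]
        screen_cfgs = [_default_selection(s, ds.scenario, kinds[s.name]) for s in screen_cfgs]
        return ds.interactome, ds.library, ds.catalog, ds.gene_sets, ds.screens, screen_cfgs, ds
    if not all([config.interactome, config.drug_targets, config.phenotypes, config.gene_sets]):
        raise ValueError("config must give either synthetic scenario or all input paths")
    interactome = io.read_interactome(config.interactome)
    library = io.read_drug_targets(config.drug_targets)
    catalog = io.read_gene_sets(config.phenotypes, format="tsv")
    gene_sets = io.read_gene_sets(config.gene_sets, format="gmt")
    screens = {
        s.name: io.read_screen_table(s.path, s.name, s.outcome_type, s.favorable_sign)
        for s in config.screens
    }
    return interactome, library, catalog, gene_sets, screens, list(config.screens), None


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory.

    Aborts with the stage name in the exception message on any stage failure.
    Consensus needs at least two screens: with one screen it is skipped and
    the omission logged as an error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    try:
        interactome, library, catalog, gene_sets, screens, screen_cfgs, ds = _load_inputs(config)
        universe = interactome.nodes
        # synthetic runs analyze the networks the outcomes were generated from
        max_depth = ds.scenario.max_depth if ds is not None else config.max_depth
        manifest: dict = {"seed": config.seed, "stages": {}}
        for name in ("interactome", "drug_targets", "phenotypes", "gene_sets"):
            p = getattr(config, name)
            if p:
                manifest[f"input_{name}_sha256"] = _hash_file(Path(p))

        stage = "networks"
        logger.info("stage=networks n_drugs=%d seed=%d", len(library), config.seed)
        networks: dict[str, pfx.DrugNetwork] = {}
        if ds is not None:
            networks = {net.drug_id: net for net in ds.networks}
        else:
            for drug_id in sorted(library.entries):
                try:
                    networks[drug_id] = pfx.build_drug_network(
                        interactome, drug_id, library.targets(drug_id), max_depth
                    )
                except pfx.DrugNotConnectedError:
                    logger.warning("drug %s not connected; skipped", drug_id)
        manifest["stages"]["networks"] = {"n_networks": len(networks)}
        if config.write_network_files:
            for net in networks.values():
                pfx.write_network_files(net, None, out / "networks")

        stage = "associations"
        logger.info("stage=associations null_iters=%d", config.null_iters)
        null_model = pfx.RandomNetworkNull(
            interactome,
            catalog,
            n_iter=config.null_iters,
            seed=config.seed,
            target_pool=library.target_pool(),
            max_depth=max_depth,
        )
        assoc_tables: dict[str, pd.DataFrame] = {}
        for drug_id, net in networks.items():
            table = pfx.associate_phenotypes(net, catalog, universe)
            table = pfx.null_filter(
                table, interactome, catalog, len(net.targets), null_model=null_model
            )
            assoc_tables[drug_id] = pfx.bh_filter(table, alpha=config.pathfx_alpha)
        merged = pd.concat(assoc_tables.values(), ignore_index=True)
        merged_out = merged.copy()
        merged_out["overlap"] = merged_out["overlap"].map(lambda t: ";".join(t))
        merged_out.to_csv(out / "associations.tsv", sep="\t", index=False)
        summary = pfx.summarize_predictions(assoc_tables)
        manifest["stages"]["associations"] = {
            "total_pairs": int(summary["total_pairs"]),
            "n_unique_drugs": int(summary["n_unique_drugs"]),
        }
        with open(out / "association_summary.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "total_pairs": int(summary["total_pairs"]),
                    "n_unique_drugs": int(summary["n_unique_drugs"]),
                    "drugs_per_phenotype": {k: int(v) for k, v in summary["drugs_per_phenotype"].items()},
                    "top_genes": {k: int(v) for k, v in summary["gene_ranking"].head(20).items()},
                },
                fh,
                indent=2,
                sort_keys=True,
            )

        stage = "regression"
        coeff_tables: dict[str, reg.CoefficientTable] = {}
        selections: dict[str, reg.GeneSelection] = {}
        for scn in screen_cfgs:
            y = screens[scn.name]
            nets = [networks[d] for d in y.drug_ids if d in networks]
            if len(nets) < 2:
                raise ValueError(f"screen {scn.name!r} matches fewer than 2 modeled drugs")
            X = reg.build_design_matrix(nets)
            spec = reg.ModelSpec(
                kind=scn.model_kind,
                alpha=scn.alpha,
                split_fraction=scn.split_fraction,
                seed=config.seed,
            )
            coeffs = reg.fit_l2(X, y, spec)
            null = reg.permutation_null(X, y, spec, n_shuffles=config.n_shuffles, seed=config.seed)
            reg.write_coefficients(coeffs, null, out / f"coefficients_{scn.name}.tsv")
            coeff_tables[scn.name] = coeffs
            selections[scn.name] = reg.select_genes(coeffs, scn.selection_rule())
            logger.info(
                "stage=regression screen=%s n_drugs=%d n_genes=%d mse=%s",
                scn.name, len(nets), len(coeffs.genes), coeffs.mse,
            )
        manifest["stages"]["regression"] = {s: len(coeff_tables[s].genes) for s in coeff_tables}

        stage = "enrichment"
        enrich_tables: dict[str, dict[str, pd.DataFrame]] = {}
        for scn in screen_cfgs:
            sel = selections[scn.name]
            enrich_tables[scn.name] = {}
            # selection bounds are favorability-oriented (the favorable bound is
            # negative for screens where negative coefficients are favorable)
            fav_list, unfav_list = sel.favorable, sel.unfavorable
            for direction, genes in (("favorable", fav_list), ("unfavorable", unfav_list)):
                if not genes:
                    logger.warning("screen %s: empty %s selection; enrichment skipped", scn.name, direction)
                    enrich_tables[scn.name][direction] = pd.DataFrame(
                        columns=["term_id", "term_name", "overlap", "p_value", "adjusted_p", "rank"]
                    )
                    continue
                table = enr.fisher_enrichment(genes, universe, gene_sets)
                enrich_tables[scn.name][direction] = table
                top = enr.top_terms(table, config.enrich_top_k).copy()
                top["overlap"] = top["overlap"].map(lambda t: ";".join(t))
                top.to_csv(out / f"enrichment_{scn.name}_{direction}.tsv", sep="\t", index=False)

        stage = "consensus"
        if len(screen_cfgs) < 2:
            logger.error("stage=consensus skipped: fewer than 2 screens")
            manifest["stages"]["consensus"] = "skipped"
        else:
            conventions = {s.name: s.favorable_sign for s in screen_cfgs}
            ctable = cns.consensus_table(coeff_tables, conventions)
            ctable.to_csv(out / "consensus.tsv", sep="\t", index=False)
            # shared genes from threshold selections, oriented by favorability
            favorability = {
                scn.name: {
                    "favorable": set(selections[scn.name].favorable),
                    "unfavorable": set(selections[scn.name].unfavorable),
                }
                for scn in screen_cfgs
            }
            report = cns.shared_genes(favorability)
            with open(out / "shared_genes.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "favorable_shared": sorted(report.favorable_shared),
                        "unfavorable_shared": sorted(report.unfavorable_shared),
                        "venn_counts": {
                            d: {" & ".join(k): v for k, v in cs.items()}
                            for d, cs in report.venn_counts.items()
                        },
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
            for direction in ("favorable", "unfavorable"):
                terms = cns.shared_terms(
                    {s: enrich_tables[s][direction] for s in enrich_tables}, alpha=config.enrich_alpha
                )
                terms.to_csv(out / f"shared_terms_{direction}.tsv", sep="\t", index=False)
            manifest["stages"]["consensus"] = {
                "favorable_shared": len(report.favorable_shared),
                "unfavorable_shared": len(report.unfavorable_shared),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
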