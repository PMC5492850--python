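"""End-to-end pipeline: simulate -> filter -> COGs -> trees -> events ->
selection -> report.

Each stage reads only the declared outputs of its upstream stages and
writes into its own subdirectory of the run directory, so any stage can
be re-run in isolation; a JSON manifest accumulates per-stage status,
output digests and wall time.  Identical config + seed give identical
output bytes.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import homology, reconcile
from .phylo import (ProteinAlignment, back_translate, bootstrap_support,
                    filter_columns)
from .reconcile import (detect_subgroups, infer_events, reconstruct_copy_numbers,
                        root_gene_tree, summarize_events)
from .selection import (BranchModel, OneRatioModel, SiteMixtureModel,
                        SwitchingModel, compare_subgroup_means,
                        label_branches_by_partition, lrt,
                        partition_positive_sites, subgroup_pairwise_omega)
from .simulate import SimulationConfig, generate_dataset, write_dataset
from .species import PARTITION, build_default_species_tree
from .tree import to_newick

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "make_report",
           "STAGES"]

STAGES = ("simulate", "filter", "cogs", "trees", "events", "selection", "report")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    mode: str = "synthetic"               # synthetic | files
    cds_fasta: str | None = None          # files mode input
    hit_table: str | None = None          # optional blast outfmt6 TSV
    stages: list = field(default_factory=lambda: list(STAGES))
    force: bool = False

    # synthetic generation
    n_families: int = 3
    n_alleles: int = 3
    n_fragments: int = 2
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    # filters
    min_len_nt: int = 400
    allele_identity: float = 0.95

    # trees
    column_score_threshold: float = 12.0
    bootstrap_reps: int = 100

    # selection
    ds_max: float = 2.0
    fit_branch_models: bool = True
    fit_site_models: bool = False         # M3 / M3+S1 are the slow fits
    switching_df: int | None = None       # override LRT df (e.g. 2)

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if not 0.0 < self.allele_identity <= 1.0:
            raise ValueError("allele_identity must lie in (0, 1]")
        if self.ds_max <= 0:
            raise ValueError("ds_max must be > 0")
        if self.min_len_nt < 0:
            raise ValueError("min_len_nt must be >= 0")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are
    rejected with a nearest-valid-key suggestion."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    errors = []
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, sorted(known), n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            errors.append(f"unknown key {key!r}{suffix}")
    if errors:
        raise ValueError("; ".join(errors))
    try:
        cfg = PipelineConfig(**raw)
        SimulationConfig(**cfg.simulation)
    except (TypeError, ValueError) as exc:
        raise ValueError(str(exc)) from None
    return cfg


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} requires missing upstream output {path}")
    return path


class _Run:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.root = Path(cfg.out_dir)
        self.root.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": {}, "seed": cfg.seed}
        self.species_tree = build_default_species_tree()

    def dir(self, stage: str) -> Path:
        d = self.root / stage
        d.mkdir(exist_ok=True)
        return d

    def record(self, stage: str, status: str, outputs: list[Path],
               t0: float, warnings: list[str] | None = None) -> None:
        self.manifest["stages"][stage] = {
            "status": status,
            "outputs": {p.name: _sha(p) for p in outputs if p.exists()},
            "seconds": round(time.time() - t0, 3),
            "warnings": warnings or [],
        }


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(run: _Run) -> None:
    cfg = run.cfg
    t0 = time.time()
    out = run.dir("simulate")
    sim_cfg = SimulationConfig(**{**cfg.simulation, "seed": cfg.seed})
    ds = generate_dataset(sim_cfg, n_families=cfg.n_families,
                          species_tree=run.species_tree,
                          n_alleles=cfg.n_alleles, n_fragments=cfg.n_fragments)
    manifest = write_dataset(ds, out)
    run.record("simulate", "ok", [out / n for n in manifest], t0)


def _stage_filter(run: _Run) -> None:
    cfg = run.cfg
    t0 = time.time()
    out = run.dir("filter")
    if cfg.mode == "synthetic":
        cds = _require(run.root / "simulate" / "cds.fasta", "filter")
    else:
        cds = _require(Path(cfg.cds_fasta), "filter")
    records = homology.load_records(cds)
    kept, report = homology.filter_sequences(
        records, min_len_nt=cfg.min_len_nt, allele_identity=cfg.allele_identity)
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    SeqIO.write([SeqRecord(Seq(r.cds), id=r.id, description="") for r in kept],
                out / "kept.fasta", "fasta")
    _write_tsv(report, out / "removals.tsv")
    run.record("filter", "ok", [out / "kept.fasta", out / "removals.tsv"], t0)


def _stage_cogs(run: _Run) -> None:
    cfg = run.cfg
    t0 = time.time()
    out = run.dir("cogs")
    kept = _require(run.root / "filter" / "kept.fasta", "cogs")
    records = homology.load_records(kept)
    species_of = {r.id: r.species for r in records}
    if cfg.hit_table:
        hits = homology.load_hit_table(cfg.hit_table, set(species_of))
    else:
        hits = homology.score_all_pairs(records)
    bets = homology.compute_bets(hits, species_of)
    cogs = homology.build_cogs(bets)
    homology.write_membership_tsv(cogs, species_of, out / "membership.tsv")
    _write_tsv(homology.cog_report(cogs, species_of, PARTITION),
               out / "cog_report.tsv")
    for cog in cogs:
        homology.write_cog_dot(cog, out / f"{cog.id}.dot")
    run.record("cogs", "ok",
               [out / "membership.tsv", out / "cog_report.tsv"], t0)


def _load_cog_members(run: _Run) -> dict[str, list[str]]:
    df = pd.read_csv(run.root / "cogs" / "membership.tsv", sep="\t")
    core = df[df["role"] == "core"]
    return {cid: sorted(g["gene_id"]) for cid, g in core.groupby("cog_id")}


def _stage_trees(run: _Run) -> None:
    cfg = run.cfg
    t0 = time.time()
    out = run.dir("trees")
    _require(run.root / "cogs" / "membership.tsv", "trees")
    kept = _require(run.root / "filter" / "kept.fasta", "trees")
    records = {r.id: r for r in homology.load_records(kept)}
    warnings_list = []
    for cog_id, members in _load_cog_members(run).items():
        if len(members) < 4:
            warnings_list.append(f"{cog_id}: fewer than 4 members, skipped")
            continue
        prots = {m: records[m].protein for m in members}
        if len({len(p) for p in prots.values()}) != 1:
            warnings_list.append(f"{cog_id}: members not aligned, skipped")
            continue
        aln = ProteinAlignment.from_strings(prots)
        filtered, kept_cols = filter_columns(aln, cfg.column_score_threshold)
        tree = bootstrap_support(filtered, n_reps=cfg.bootstrap_reps,
                                 seed=cfg.seed)
        rooted = root_gene_tree(tree, run.species_tree)
        with open(out / f"{cog_id}.nwk", "w") as fh:
            fh.write(to_newick(rooted, support_as_label=True) + "\n")
        _write_tsv(pd.DataFrame({"kept_column": kept_cols}),
                   out / f"{cog_id}.columns.tsv")
    run.record("trees", "ok", sorted(out.glob("*.nwk")), t0, warnings_list)


def _stage_events(run: _Run) -> None:
    t0 = time.time()
    out = run.dir("events")
    trees_dir = _require(run.root / "trees", "events")
    from .tree import parse_newick
    tables, recs = [], []
    for nwk in sorted(trees_dir.glob("*.nwk")):
        cog_id = nwk.stem
        rooted = parse_newick(nwk.read_text())
        sgs = detect_subgroups(rooted, run.species_tree)
        table, rec = infer_events(rooted, run.species_tree, sgs, cog_id=cog_id)
        tables.append(table)
        recs.append(rec)
    if not recs:
        raise FileNotFoundError("stage 'events' found no gene trees in "
                                f"{trees_dir}")
    _write_tsv(pd.concat(tables, ignore_index=True) if tables else
               pd.DataFrame(), out / "events.tsv")
    _write_tsv(summarize_events(tables), out / "summary.tsv")
    profile = reconstruct_copy_numbers(recs, run.species_tree)
    _write_tsv(profile.to_frame(), out / "copy_numbers.tsv")
    run.record("events", "ok", [out / "events.tsv", out / "summary.tsv",
                                out / "copy_numbers.tsv"], t0)


def _stage_selection(run: _Run) -> None:
    cfg = run.cfg
    t0 = time.time()
    out = run.dir("selection")
    trees_dir = _require(run.root / "trees", "selection")
    kept = _require(run.root / "filter" / "kept.fasta", "selection")
    from .tree import parse_newick
    records = {r.id: r for r in homology.load_records(kept)}
    pair_rows, branch_rows, site_rows = [], [], []
    for nwk in sorted(trees_dir.glob("*.nwk")):
        cog_id = nwk.stem
        rooted = parse_newick(nwk.read_text())
        cols = pd.read_csv(trees_dir / f"{cog_id}.columns.tsv", sep="\t")
        kept_cols = cols["kept_column"].to_numpy()
        members = rooted.leaf_names()
        prots = {m: records[m].protein for m in members}
        aln = ProteinAlignment.from_strings(prots)
        codon_aln = back_translate(aln, {m: records[m].cds for m in members},
                                   kept_cols)
        sgs = detect_subgroups(rooted, run.species_tree)
        # pairwise omega within subgroups + dicot/grass comparison
        sub = subgroup_pairwise_omega(codon_aln, sgs, ds_max=cfg.ds_max)
        d_vals = np.concatenate([s.omegas for s in sub if s.partition == "dicot"]
                                or [np.array([])])
        g_vals = np.concatenate([s.omegas for s in sub if s.partition == "grass"]
                                or [np.array([])])
        cmp_res = (compare_subgroup_means(d_vals, g_vals)
                   if d_vals.size and g_vals.size else None)
        for s in sub:
            pair_rows.append({
                "cog_id": cog_id, "subgroup": s.subgroup_id,
                "partition": s.partition, "n_pairs": len(s.pairs),
                "n_saturated": s.n_discarded_saturated,
                "mean_omega": s.mean_omega,
                "comparison_p": cmp_res["pvalue"] if cmp_res else np.nan,
                "comparison_label": cmp_res["label"] if cmp_res else "",
                "caveat": s.caveat})
        if cfg.fit_branch_models:
            one = OneRatioModel(codon_aln, rooted).fit()
            labels = label_branches_by_partition(rooted, PARTITION)
            two = BranchModel(codon_aln, rooted, labels).fit(init_from=one)
            test = lrt(one, two)
            branch_rows.append({
                "cog_id": cog_id, "neg_lnl_one": one.neg_loglik,
                "omega_one": one.params["omega"],
                "neg_lnl_branch": two.neg_loglik,
                **{f"omega_{c}": w for c, w in two.params["omega"].items()},
                "lrt_stat": test.statistic, "lrt_df": test.df,
                "lrt_p": test.pvalue})
        if cfg.fit_site_models:
            m3 = SiteMixtureModel(codon_aln, rooted, 3).fit()
            s1 = SwitchingModel(codon_aln, rooted, 3).fit(init_from=m3)
            test = lrt(m3, s1, df=cfg.switching_df)
            sites = partition_positive_sites(s1, PARTITION,
                                             kept_column_map=kept_cols)
            site_rows.append({
                "cog_id": cog_id,
                "neg_lnl_m3": m3.neg_loglik, "neg_lnl_s1": s1.neg_loglik,
                "p1": m3.params["proportions"][0],
                "p2": m3.params["proportions"][1],
                "p3": m3.params["proportions"][2],
                "w1": m3.params["omegas"][0], "w2": m3.params["omegas"][1],
                "w3": m3.params["omegas"][2],
                "delta": s1.params["delta"],
                "lrt_stat": test.statistic, "lrt_df": test.df,
                "lrt_p": test.pvalue,
                "dicot_sites": ";".join(map(str, sites["dicot"]["site"])),
                "grass_sites": ";".join(map(str, sites["grass"]["site"])),
                "shared_sites": ";".join(map(str, sites["shared"]["site"]))})
    _write_tsv(pd.DataFrame(pair_rows), out / "subgroup_omega.tsv")
    if branch_rows:
        _write_tsv(pd.DataFrame(branch_rows), out / "branch_models.tsv")
        (out / "branch_models.json").write_text(
            json.dumps(branch_rows, indent=2, default=float))
    if site_rows:
        _write_tsv(pd.DataFrame(site_rows), out / "site_models.tsv")
        (out / "site_models.json").write_text(
            json.dumps(site_rows, indent=2, default=float))
    run.record("selection", "ok", sorted(out.glob("*.tsv")), t0)


def make_report(results_dir) -> dict[str, Path]:
    """Assemble the three summary tables (duplication/loss, branch-model,
    site-model) and the copy-number profile from stage outputs.

    Missing upstream analyses yield tables with explicit "missing"
    cells, never silently dropped rows."""
    root = Path(results_dir)
    out = root / "report"
    out.mkdir(exist_ok=True)
    paths = {}

    events_summary = root / "events" / "summary.tsv"
    if events_summary.exists():
        dup_loss = pd.read_csv(events_summary, sep="\t")
    else:
        dup_loss = pd.DataFrame([{"cog_id": "missing"}])
    _write_tsv(dup_loss, out / "table_duplication_loss.tsv")
    paths["duplication_loss"] = out / "table_duplication_loss.tsv"

    cog_ids = []
    membership = root / "cogs" / "membership.tsv"
    if membership.exists():
        cog_ids = sorted(pd.read_csv(membership, sep="\t")["cog_id"].unique())

    branch = root / "selection" / "branch_models.tsv"
    if branch.exists():
        btab = pd.read_csv(branch, sep="\t")
    else:
        btab = pd.DataFrame({"cog_id": cog_ids})
        for c in ("neg_lnl_one", "omega_one", "neg_lnl_branch", "lrt_p"):
            btab[c] = "missing"
    _write_tsv(btab, out / "table_branch_models.tsv")
    paths["branch_models"] = out / "table_branch_models.tsv"

    site = root / "selection" / "site_models.tsv"
    if site.exists():
        stab = pd.read_csv(site, sep="\t")
    else:
        stab = pd.DataFrame({"cog_id": cog_ids})
        for c in ("neg_lnl_m3", "neg_lnl_s1", "delta", "lrt_p",
                  "dicot_sites", "grass_sites"):
            stab[c] = "missing"
    _write_tsv(stab, out / "table_site_models.tsv")
    paths["site_models"] = out / "table_site_models.tsv"

    copy_numbers = root / "events" / "copy_numbers.tsv"
    if copy_numbers.exists():
        _write_tsv(pd.read_csv(copy_numbers, sep="\t"),
                   out / "figure_copy_numbers.tsv")
        paths["copy_numbers"] = out / "figure_copy_numbers.tsv"
    return paths


def _stage_report(run: _Run) -> None:
    t0 = time.time()
    paths = make_report(run.root)
    run.record("report", "ok", list(paths.values()), t0)


_STAGE_FUNCS = {"simulate": _stage_simulate, "filter": _stage_filter,
                "cogs": _stage_cogs, "trees": _stage_trees,
                "events": _stage_events, "selection": _stage_selection,
                "report": _stage_report}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    A stage whose outputs already exist is skipped unless ``cfg.force``;
    disabled stages are recorded as "skipped".  Failures abort downstream
    stages with a diagnostic naming the stage."""
    run = _Run(cfg)
    for stage in STAGES:
        if stage not in cfg.stages:
            run.manifest["stages"][stage] = {"status": "skipped (disabled)"}
            continue
        if cfg.mode == "files" and stage == "simulate":
            run.manifest["stages"][stage] = {"status": "skipped (files mode)"}
            continue
        stage_dir = run.root / stage
        if (not cfg.force and stage_dir.exists()
                and any(stage_dir.iterdir())):
            run.manifest["stages"][stage] = {"status": "cached"}
            continue
        _STAGE_FUNCS[stage](run)
    manifest_path = run.root / "manifest.json"
    cfg_dict = dataclasses.asdict(cfg)
    (run.root / "config.yaml").write_text(yaml.safe_dump(cfg_dict, sort_keys=False))
    manifest_path.write_text(json.dumps(run.manifest, indent=2, sort_keys=True))
    return run.manifest
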