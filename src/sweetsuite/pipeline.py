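"""End-to-end orchestration with a single validated configuration.

``run_all`` executes the stages in the fixed order generate -> screen ->
ssn -> architecture -> msa_profile -> coevolution -> phylo (energetics is
independent and only runs when a component table is supplied), writing
every stage's tables under ``output_dir`` and returning a JSON-serialisable
run report that records parameters, seeds, output paths and row counts.
Reruns with an identical configuration reproduce identical outputs.

The module also ships the transcribed mutation-outcome table for the 19
most conserved SWEET positions (rank, relative conservation, OsSWEET2b and
AtSWEET1 numbering, substitution tested, and whether it abolished, reduced
or did not affect glucose transport) together with a residue-region
annotation (extrafacial gate / binding pocket / intrafacial gate) used to
label outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import architecture, coevolution, energetics, msa, phylo, screen, ssn, synthetic
from .records import ProteinRecord, read_fasta, write_fasta, write_metadata

IMPACT_LABELS = ("Abolish", "Reduce", "No effect")

#: Known configuration keys per section; anything else is rejected.
_SCHEMA: dict[str, set[str]] = {
    "inputs": {"fasta", "metadata"},
    "generate": {
        "enabled", "seed", "n_families", "seqs_per_family", "substitution_rate",
        "n_invariant", "n_covarying", "fragment_rate", "duplicate_rate", "tmh_count",
    },
    "screen": {
        "enabled", "min_tmh", "fragment_max_fraction", "motif_mode",
        "window", "threshold", "min_helix_len", "merge_gap",
    },
    "ssn": {"enabled", "evalue_cutoff", "min_cluster_size"},
    "architecture": {"enabled", "fusion_identity_threshold"},
    "msa_profile": {"enabled", "reference", "weighting"},
    "coevolution": {"enabled", "mi_threshold", "n_shuffles", "seed", "max_pairs"},
    "phylo": {"enabled", "n_replicates", "seed", "model"},
    "energetics": {"enabled", "table", "gamma", "beta", "tds"},
}
_TOP_LEVEL = set(_SCHEMA) | {"output_dir"}


class ConfigError(ValueError):
    """Configuration contains unknown keys or invalid values."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries a machine-readable code."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage:{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``_SCHEMA`` for known keys)."""

    output_dir: str = "sweetsuite_out"
    sections: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - _TOP_LEVEL
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        sections = {}
        for name, keys in _SCHEMA.items():
            section = raw.get(name, {}) or {}
            if not isinstance(section, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            bad = set(section) - keys
            if bad:
                raise ConfigError(
                    f"unknown keys in section {name!r}: {sorted(bad)}"
                )
            sections[name] = dict(section)
        return cls(output_dir=raw.get("output_dir", "sweetsuite_out"), sections=sections)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def section(self, name: str) -> dict[str, Any]:
        return self.sections.get(name, {})

    def enabled(self, name: str) -> bool:
        return bool(self.section(name).get("enabled", False))

    def to_dict(self) -> dict[str, Any]:
        return {"output_dir": self.output_dir, **self.sections}


def _validate_report(report: dict, schema: dict) -> None:
    """Minimal structural validation of the run report against the packaged
    schema (required keys and JSON types only)."""
    def check(obj, sch, path="report"):
        t = sch.get("type")
        if t == "object":
            if not isinstance(obj, dict):
                raise ValueError(f"{path}: expected object")
            for key in sch.get("required", []):
                if key not in obj:
                    raise ValueError(f"{path}: missing required key {key!r}")
            for key, sub in sch.get("properties", {}).items():
                if key in obj:
                    check(obj[key], sub, f"{path}.{key}")
        elif t == "array":
            if not isinstance(obj, list):
                raise ValueError(f"{path}: expected array")
            for i, item in enumerate(obj):
                check(item, sch.get("items", {}), f"{path}[{i}]")
        elif t == "string":
            if not isinstance(obj, str):
                raise ValueError(f"{path}: expected string")
    check(report, schema)


def report_schema() -> dict:
    with resources.files("sweetsuite.data").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def run_all(config: RunConfig) -> dict:
    """Run the enabled stages in order and return the validated run report."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": config.to_dict(), "stages": []}

    def record(name: str, parameters: dict, outputs: dict[str, str], row_counts: dict[str, int]):
        report["stages"].append(
            {
                "name": name,
                "parameters": parameters,
                "outputs": {k: str(v) for k, v in outputs.items()},
                "row_counts": {k: int(v) for k, v in row_counts.items()},
            }
        )

    records: Optional[list[ProteinRecord]] = None
    truth: Optional[synthetic.TruthTable] = None

    if config.enabled("generate"):
        p = {k: v for k, v in config.section("generate").items() if k != "enabled"}
        scenario, templates = synthetic.demo_scenario(**p)
        records, truth = synthetic.generate(scenario, templates)
        fasta = out_dir / "synthetic.fasta"
        meta = out_dir / "synthetic_metadata.tsv"
        seq_truth = out_dir / "truth_sequences.tsv"
        fam_truth = out_dir / "truth_families.tsv"
        write_fasta(records, fasta)
        write_metadata(records, meta)
        truth.write(seq_truth, fam_truth)
        record(
            "generate", p,
            {"fasta": fasta, "metadata": meta, "truth_sequences": seq_truth,
             "truth_families": fam_truth},
            {"records": len(records)},
        )
    elif config.section("inputs").get("fasta"):
        records = read_fasta(
            config.section("inputs")["fasta"],
            config.section("inputs").get("metadata"),
        )

    def need_records(stage: str) -> list[ProteinRecord]:
        if not records:
            raise StageError(stage, "no input records: enable generate or set inputs.fasta")
        return records

    kept = records
    if config.enabled("screen"):
        p = {k: v for k, v in config.section("screen").items() if k != "enabled"}
        rep = screen.apply_filters(need_records("screen"), **p)
        path = out_dir / "screen_report.tsv"
        rep.to_tsv(path)
        fasta = out_dir / "screened.fasta"
        write_fasta(rep.kept, fasta)
        kept = rep.kept
        record("screen", p, {"report": path, "fasta": fasta},
               {"input": len(records), "kept": len(rep.kept)})

    if config.enabled("ssn"):
        p = {k: v for k, v in config.section("ssn").items() if k != "enabled"}
        graph = ssn.build_network(
            need_records("ssn") if kept is None else kept,
            evalue_cutoff=float(p.get("evalue_cutoff", 1e-55)),
        )
        ssn.label_clusters(graph, min_cluster_size=int(p.get("min_cluster_size", 10)))
        edge_path = out_dir / "ssn_edges.tsv"
        member_path = out_dir / "ssn_clusters.tsv"
        graphml = out_dir / "ssn.graphml"
        graph.edge_table().to_csv(edge_path, sep="\t", index=False)
        graph.membership_table().to_csv(member_path, sep="\t", index=False)
        graph.write_graphml(graphml)
        record("ssn", p, {"edges": edge_path, "clusters": member_path, "graphml": graphml},
               {"edges": len(graph.edges), "clusters": len(graph.clusters),
                "labeled": len(graph.labels)})

    if config.enabled("architecture"):
        p = {k: v for k, v in config.section("architecture").items() if k != "enabled"}
        rows = []
        for rec in need_records("architecture") if kept is None else kept:
            topo = screen.predict_tmh(rec.sequence)
            if topo.count == 0:
                continue
            call = architecture.call_architecture(rec.accession, topo, rec.sequence)
            rows.append(
                {
                    "accession": rec.accession,
                    "tmh_count": call.tmh_count,
                    "arch_class": call.arch_class,
                    "units": ";".join(
                        f"{u.seq_span[0]}-{u.seq_span[1]}:{u.unit_type}"
                        for u in call.units
                    ),
                }
            )
        path = out_dir / "architecture.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        record("architecture", p, {"calls": path}, {"calls": len(rows)})

    alignment: Optional[msa.MSA] = None
    if config.enabled("msa_profile"):
        p = {k: v for k, v in config.section("msa_profile").items() if k != "enabled"}
        src = need_records("msa_profile") if kept is None else kept
        alignment = msa.align(src)
        aln_path = out_dir / "alignment.fasta"
        alignment.to_fasta(aln_path)
        profile = msa.conservation(alignment, weighting=p.get("weighting", "none"))
        cons_path = out_dir / "conservation.tsv"
        profile.to_tsv(cons_path)
        logo_path = out_dir / "logo_matrix.tsv"
        msa.logo_matrix(alignment).to_csv(logo_path, sep="\t", index=False)
        record("msa_profile", p, {"alignment": aln_path, "conservation": cons_path,
                                  "logo": logo_path},
               {"rows": alignment.n_rows, "columns": alignment.n_columns})

    if config.enabled("coevolution"):
        if alignment is None:
            raise StageError("coevolution", "requires the msa_profile stage")
        p = {k: v for k, v in config.section("coevolution").items() if k != "enabled"}
        all_pairs = coevolution.mutual_information(alignment)
        max_pairs = int(p.get("max_pairs", 200))
        top = sorted(all_pairs, key=lambda q: (-q.mi_raw, q.col_a, q.col_b))[:max_pairs]
        coevolution.mi_zscores(
            top, alignment,
            n_shuffles=int(p.get("n_shuffles", 50)),
            seed=int(p.get("seed", 0)),
        )
        sig = coevolution.significant_pairs(
            top, mi_threshold=float(p.get("mi_threshold", 6.5))
        )
        if sig:
            coevolution.classify_edges(sig)
        cmi = coevolution.cumulative_mi(sig, alignment.n_columns)
        pair_path = out_dir / "mi_pairs.tsv"
        coevolution.pair_table(top).to_csv(pair_path, sep="\t", index=False)
        cmi_path = out_dir / "cmi.tsv"
        pd.DataFrame(
            {"column": range(1, alignment.n_columns + 1), "cMI": cmi}
        ).to_csv(cmi_path, sep="\t", index=False)
        record("coevolution", p, {"pairs": pair_path, "cmi": cmi_path},
               {"scored": len(top), "significant": len(sig)})

    if config.enabled("phylo"):
        if alignment is None:
            raise StageError("phylo", "requires the msa_profile stage")
        p = {k: v for k, v in config.section("phylo").items() if k != "enabled"}
        tree = phylo.bootstrap(
            alignment,
            n_replicates=int(p.get("n_replicates", 100)),
            seed=int(p.get("seed", 0)),
            model=p.get("model", "p"),
        )
        tree_path = out_dir / "tree.nwk"
        tree_path.write_text(tree.to_newick() + "\n")
        record("phylo", p, {"tree": tree_path},
               {"leaves": len(tree.leaf_names())})

    if config.enabled("energetics"):
        p = {k: v for k, v in config.section("energetics").items() if k != "enabled"}
        table = p.get("table")
        if not table:
            raise StageError("energetics", "energetics.table (component TSV) is required")
        comp = energetics.EnergyComponents.from_tsv(
            table,
            gamma=float(p.get("gamma", energetics.DEFAULT_GAMMA)),
            beta=float(p.get("beta", energetics.DEFAULT_BETA)),
            tds=float(p.get("tds", 0.0)),
        )
        rows = energetics.favorability(energetics.combine(comp))
        path = out_dir / "energy_decomposition.tsv"
        rows.to_csv(path, sep="\t", index=False)
        record("energetics", p, {"decomposition": path}, {"rows": len(rows)})

    _validate_report(report, report_schema())
    report_path = out_dir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


# ---------------------------------------------------------------------------
# Mutation-outcome fixture
# ---------------------------------------------------------------------------

def load_mutation_table() -> pd.DataFrame:
    """The packaged 19-row mutation-outcome table (most conserved SWEET
    residues, AtSWEET1 point-mutant phenotypes), with region annotation."""
    data = resources.files("sweetsuite.data")
    table = pd.read_csv(data.joinpath("mutation_outcomes.tsv"), sep="\t")
    regions = pd.read_csv(data.joinpath("residue_regions.tsv"), sep="\t")
    return table.merge(
        regions[["position_at", "region"]], on="position_at", how="left"
    )


def summarize_mutation_table(
    rows: pd.DataFrame, impact_filter: str
) -> tuple[int, list[str]]:
    """Count and list the residues with a given impact label.

    Residues are reported as AtSWEET1 residue+position (e.g. 'S54').
    """
    if impact_filter not in IMPACT_LABELS:
        raise ValueError(
            f"unknown impact label {impact_filter!r}; expected one of {IMPACT_LABELS}"
        )
    hits = rows[rows["impact"] == impact_filter]
    residues = [
        f"{r.residue_at}{r.position_at}" for r in hits.itertuples(index=False)
    ]
    return len(hits), residues
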