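"""End-to-end pipeline: load-or-simulate -> patterns -> breakpoints ->
clusters -> cladogram -> (optional) Ka and the breakpoint-Ka correlation.

Everything is deterministic given the config and seed; every output table
carries a header naming the producing version and a hash of the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .breakpoints import breakpoint_matrix
from .clusters import GeneCluster, build_cladogram, derived_clusters
from .gene_order import (
    ancestral_arrangement,
    dedup_patterns,
    parse_genbank,
    read_orders,
    write_patterns_tsv,
)
from .kaks import correlate_bp_ka, kaks_table

log = logging.getLogger("mitorearr")


@dataclass
class PipelineConfig:
    orders_path: Optional[str] = None
    genbank_path: Optional[str] = None
    ancestor: str = "anc"  # "anc" = packaged ancestral arrangement, or a path
    outgroup_path: Optional[str] = None
    clusters_path: Optional[str] = None  # named clusters TSV
    max_insertions: int = 0
    min_len: int = 2
    max_len: int = 8
    alignment_path: Optional[str] = None  # codon-aligned FASTA
    reference_id: Optional[str] = None
    code: int = 5
    simulate: Optional[dict] = None  # {'shape': 'balanced:8', 'rates': {...}}
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    _extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.max_insertions < 0 or self.min_len < 2:
            raise ValueError("tolerances must be >= 0 and min_len >= 2")
        for label, path in (
            ("orders", self.orders_path),
            ("genbank", self.genbank_path),
            ("outgroup", self.outgroup_path),
            ("clusters", self.clusters_path),
            ("alignment", self.alignment_path),
        ):
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.ancestor != "anc" and not os.path.exists(self.ancestor):
            raise FileNotFoundError(f"ancestor file not found: {self.ancestor}")
        if not (
            self.orders_path or self.genbank_path or self.simulate
        ):
            raise ValueError("need orders_path, genbank_path or simulate config")

    def config_hash(self) -> str:
        # hash only the analysis-determining fields, not output/log locations
        payload = {
            k: v for k, v in self.__dict__.items()
            if not k.startswith("_") and k not in ("out_dir", "log_level")
        }
        return hashlib.md5(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_named_clusters(path: str) -> list[tuple[GeneCluster, int]]:
    """Read a named-cluster TSV: label<TAB>space-separated genes<TAB>tolerance."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "label\t")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed cluster line: {line!r}")
            tokens = parts[1].split()
            tol = int(parts[2]) if len(parts) > 2 and parts[2] else 0
            out.append((GeneCluster(tokens), tol))
    return out


def _read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a summary dict (also written as report.txt)."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    header = f"# mitorearr {__version__} config={config.config_hash()}\n"

    def out(name):
        return os.path.join(config.out_dir, name)

    # stage: inputs
    if config.orders_path:
        orders = read_orders(config.orders_path)
    elif config.genbank_path:
        orders = parse_genbank(config.genbank_path)
    else:
        from .simulate import simulate_rearrangements, write_orders

        sim_cfg = config.simulate or {}
        tree = sim_cfg.get("tree")
        if tree is None:
            from .trees import balanced_newick

            shape, _, k = sim_cfg.get("shape", "balanced:8").partition(":")
            if shape != "balanced":
                from .simulate import _shape_newick
                import numpy as np

                tree = _shape_newick(
                    int(k or 8), shape, np.random.default_rng([config.seed, 7])
                )
            else:
                tree = balanced_newick(int(k or 8))
        result = simulate_rearrangements(
            tree, rates=sim_cfg.get("rates", {"inversion": 0.5}),
            seed=config.seed,
        )
        orders = list(result.tip_orders.values())
        write_orders(orders, out("simulated_orders.txt"))
    log.info("stage=input n_orders=%d", len(orders))
    if config.ancestor == "anc":
        ancestor = ancestral_arrangement()
    else:
        anc_orders = read_orders(config.ancestor)
        if len(anc_orders) != 1:
            raise ValueError("ancestor file must contain exactly one order")
        ancestor = anc_orders[0]
    outgroup = (
        read_orders(config.outgroup_path) if config.outgroup_path else []
    )

    # stage: arrangement patterns
    patterns = dedup_patterns(orders)
    with open(out("patterns.tsv"), "w") as fh:
        fh.write(header)
        write_patterns_tsv(patterns, fh)
    log.info("stage=patterns n_patterns=%d", len(patterns))

    # stage: breakpoints vs ancestor
    bp = breakpoint_matrix(orders, reference=ancestor)
    with open(out("breakpoints.tsv"), "w") as fh:
        fh.write(header)
        bp.to_csv(fh, sep="\t", index=False)
    log.info(
        "stage=breakpoints min=%d max=%d",
        bp["breakpoints"].min(), bp["breakpoints"].max(),
    )

    # stage: derived clusters + cladogram
    named = (
        load_named_clusters(config.clusters_path)
        if config.clusters_path else None
    )
    shared_derived = derived_clusters(
        orders, ancestor, outgroup,
        max_insertions=config.max_insertions,
        min_len=config.min_len, max_len=None,
    )
    cladogram = build_cladogram(
        orders, ancestor, outgroup,
        named_clusters=named,
        max_insertions=config.max_insertions,
        min_len=config.min_len, max_len=config.max_len,
    )
    with open(out("cladogram.nwk"), "w") as fh:
        fh.write(cladogram.to_newick() + "\n")
    with open(out("clades.tsv"), "w") as fh:
        fh.write(header)
        fh.write("taxa\tn_taxa\tsupport\tclusters\texclusive\n")
        for clade in cladogram.clades:
            fh.write(
                f"{','.join(sorted(clade.taxa))}\t{len(clade.taxa)}\t"
                f"{clade.support}\t"
                f"{'|'.join(c.label for c in clade.supporting_clusters)}\t"
                f"{clade.exclusive}\n"
            )
    with open(out("conflicts.tsv"), "w") as fh:
        fh.write(header)
        fh.write("taxa\tclusters\tsupport\tconflicts_with\n")
        for c in cladogram.conflicts:
            fh.write(
                f"{c['taxa']}\t{c['clusters']}\t{c['support']}\t"
                f"{c['conflicts_with']}\n"
            )
    log.info(
        "stage=cladogram clades=%d conflicts=%d",
        len(cladogram.clades), len(cladogram.conflicts),
    )

    # stage: Ka and the breakpoint-Ka correlation (optional)
    correlation = None
    if config.alignment_path:
        seqs = _read_fasta(config.alignment_path)
        ref = config.reference_id or ancestor.taxon_id
        table = kaks_table(seqs, ref, table_id=config.code)
        bp_by_taxon = dict(zip(bp["taxon_a"], bp["breakpoints"]))
        table["breakpoints"] = table["taxon"].map(bp_by_taxon)
        table = table.dropna(subset=["breakpoints", "Ka"])
        with open(out("kaks.tsv"), "w") as fh:
            fh.write(header)
            table.to_csv(fh, sep="\t", index=False)
        if len(table) >= 3:
            correlation = correlate_bp_ka(table["breakpoints"], table["Ka"])
            log.info(
                "stage=correlation n=%d r=%.3f", correlation.n, correlation.r
            )

    summary = {
        "n_taxa": len(orders),
        "n_patterns": len(patterns),
        "bp_min": int(bp["breakpoints"].min()),
        "bp_max": int(bp["breakpoints"].max()),
        "n_derived_clusters_all_taxa": len(shared_derived),
        "n_clades": len(cladogram.clades),
        "n_conflicts": len(cladogram.conflicts),
        "cladogram": cladogram.to_newick(),
    }
    if correlation is not None:
        summary.update(
            {
                "pearson_r": correlation.r,
                "df": correlation.df,
                "p_value": correlation.p_value,
            }
        )
    with open(out("report.txt"), "w") as fh:
        fh.write(header)
        for key, val in summary.items():
            fh.write(f"{key}\t{val}\n")
    return summary
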