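"""End-to-end orchestration: run enabled stages in dependency order from a
single config and write TSV outputs plus a reproducibility manifest.

The manifest records every parameter, seed, input checksum and output
checksum/row count, so a run can be reproduced bit-identically from it.
Timings go to stderr only and never enter the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation, dormancy, evolution, family_scan, homologs, phylo
from .core_io import read_fasta, read_gene_table, translate_cds, write_fasta

__all__ = ["RunConfig", "PipelineError", "ConfigError", "StageError",
           "run_pipeline", "write_demo_inputs"]

logger = logging.getLogger("genefam")

STAGE_ORDER = [
    "identify", "props", "phylo", "homologs", "kaks",
    "clusters", "promoter", "germination", "expression",
]


class PipelineError(RuntimeError):
    pass


class ConfigError(PipelineError):
    """Invalid configuration (missing files, bad parameters)."""


class StageError(PipelineError):
    """A stage failed or a dependency was not satisfied."""


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    stages: dict = field(default_factory=dict)   # stage name -> bool
    inputs: dict = field(default_factory=dict)   # role -> path
    params: dict = field(default_factory=dict)

    DEFAULT_PARAMS = {
        "scan_mode": "strict",
        "bootstrap": 100,
        "distance_model": "poisson",
        "lambda_rate": 6.5e-9,
        "window": 30,
        "step": 3,
        "min_identity": 75.0,
        "min_coverage": 75.0,
        "max_span": 200_000,
        "min_genes": 2,
    }

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config keys: {exc}") from None

    def param(self, name: str):
        return self.params.get(name, self.DEFAULT_PARAMS[name])

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for role, path in self.inputs.items():
            if not Path(path).exists():
                raise ConfigError(f"input {role!r} does not exist: {path}")
        if self.param("window") < 1 or self.param("step") < 1:
            raise ConfigError("window and step must be >= 1")
        if self.param("lambda_rate") <= 0:
            raise ConfigError("lambda_rate must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _rows(path: Path) -> int:
    with open(path) as fh:
        return max(0, sum(1 for _ in fh) - 1)  # minus header


def _need(config: RunConfig, role: str, stage: str) -> Path:
    if role not in config.inputs:
        raise StageError(f"stage {stage!r} requires input {role!r}")
    return Path(config.inputs[role])


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; return the manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "params": {k: config.param(k) for k in RunConfig.DEFAULT_PARAMS},
        "inputs": {
            role: {"path": str(p), "sha256": _sha256(Path(p))}
            for role, p in sorted(config.inputs.items())
        },
        "stages": {},
    }
    pair_table_path: Path | None = None

    for stage in STAGE_ORDER:
        if not config.stages.get(stage, False):
            continue
        t0 = time.perf_counter()
        outputs: list[Path] = []

        if stage == "identify":
            proteins = read_fasta(_need(config, "proteins_fasta", stage), "protein")
            hits = family_scan.scan_sequence_set(
                proteins, mode=config.param("scan_mode")
            )
            out = outdir / "vq_hits.tsv"
            with open(out, "w") as fh:
                fh.write("gene_id\tposition\tmatched\tdomain_type\tvh_variant\n")
                for h in hits:
                    fh.write(f"{h.gene_id}\t{h.position}\t{h.matched}\t"
                             f"{h.domain_type}\t{int(h.vh_variant)}\n")
            outputs.append(out)

        elif stage == "props":
            proteins = read_fasta(_need(config, "proteins_fasta", stage), "protein")
            out = outdir / "protein_properties.tsv"
            with open(out, "w") as fh:
                fh.write("gene_id\tlength_aa\tmw_da\tpi\n")
                for name, seq in proteins.items():
                    p = family_scan.protein_properties(seq)
                    fh.write(f"{name}\t{p.length_aa}\t{p.mw}\t{p.pi}\n")
            outputs.append(out)

        elif stage == "phylo":
            if "alignment_fasta" in config.inputs:
                aligned = read_fasta(config.inputs["alignment_fasta"], "protein")
                aln = phylo.Alignment(list(aligned.items()), "protein")
            else:
                proteins = read_fasta(
                    _need(config, "proteins_fasta", stage), "protein"
                )
                aln = phylo.progressive_align(proteins)
            tree = phylo.bootstrap_support(
                aln,
                replicates=config.param("bootstrap"),
                seed=config.seed,
                model=config.param("distance_model"),
            )
            out = outdir / "tree.nwk"
            out.write_text(tree.newick() + "\n")
            outputs.append(out)

        elif stage == "homologs":
            cds = read_fasta(_need(config, "cds_fasta", stage), "nucleotide")
            pairs = homologs.find_homolog_pairs(
                cds,
                min_identity=config.param("min_identity"),
                min_coverage=config.param("min_coverage"),
            )
            out = outdir / "homolog_pairs.tsv"
            with open(out, "w") as fh:
                fh.write("gene_a\tgene_b\tkind\tidentity\tcoverage\tscore\n")
                for p in pairs:
                    fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.kind}\t"
                             f"{p.identity:.2f}\t{p.coverage:.2f}\t{p.score}\n")
            outputs.append(out)
            pair_table_path = out

        elif stage == "kaks":
            cds = read_fasta(_need(config, "cds_fasta", stage), "nucleotide")
            if pair_table_path is None:
                if "pairs_tsv" not in config.inputs:
                    raise StageError(
                        "stage 'kaks' needs the 'homologs' stage enabled "
                        "or a 'pairs_tsv' input"
                    )
                pair_table_path = Path(config.inputs["pairs_tsv"])
            pairs = homologs.read_pair_table(pair_table_path)
            clock = evolution.ClockConfig(config.param("lambda_rate"))
            out = outdir / "kaks.tsv"
            win_out = outdir / "kaks_windows.tsv"
            window, step = config.param("window"), config.param("step")
            with open(out, "w") as fh, open(win_out, "w") as wfh:
                fh.write("pair\tka\tks\tka_ks\tselection\tdate_mya\n")
                wfh.write("pair\twindow_start_codon\tka\tks\tka_ks\n")
                for p in pairs:
                    if p.gene_a not in cds or p.gene_b not in cds:
                        raise StageError(
                            f"stage 'kaks': pair {p.gene_a}/{p.gene_b} "
                            "missing from the CDS input"
                        )
                    rows = _codon_align_pair(cds[p.gene_a], cds[p.gene_b])
                    r = evolution.nei_gojobori(rows[0], rows[1])
                    date = evolution.divergence_time(r.ks, clock)
                    fmt = lambda v: "NA" if v is None else f"{v:.4f}"
                    fh.write(
                        f"{p.gene_a}/{p.gene_b}\t{fmt(r.ka)}\t{fmt(r.ks)}\t"
                        f"{fmt(r.ratio)}\t{r.selection_class}\t{fmt(date)}\n"
                    )
                    n_codons = len(rows[0]) // 3
                    if window <= n_codons:
                        for start, ka, ks, ratio in evolution.sliding_window_kaks(
                            rows[0], rows[1], window, step
                        ):
                            wfh.write(
                                f"{p.gene_a}/{p.gene_b}\t{start}\t{fmt(ka)}\t"
                                f"{fmt(ks)}\t{fmt(ratio)}\n"
                            )
            outputs += [out, win_out]

        elif stage == "clusters":
            genes = read_gene_table(_need(config, "gene_table", stage))
            found = annotation.detect_clusters(
                genes,
                max_span=config.param("max_span"),
                min_genes=config.param("min_genes"),
            )
            out = outdir / "gene_clusters.tsv"
            with open(out, "w") as fh:
                fh.write("chromosome\tspan_bp\tmembers\n")
                for c in found:
                    fh.write(f"{c.chromosome}\t{c.span}\t{','.join(c.members)}\n")
            dist = annotation.chromosome_distribution(genes)
            out2 = outdir / "chromosome_distribution.tsv"
            with open(out2, "w") as fh:
                fh.write("chromosome\tcount\n")
                for chrom, n in dist.items():
                    fh.write(f"{chrom}\t{n}\n")
            outputs += [out, out2]

        elif stage == "promoter":
            promoters = read_fasta(
                _need(config, "promoters_fasta", stage), "nucleotide"
            )
            hits = []
            for name, seq in promoters.items():
                hits += annotation.scan_cis_elements(seq, gene_id=name)
            out = outdir / "cis_hits.tsv"
            with open(out, "w") as fh:
                fh.write("gene_id\telement\tcategory\tposition\tstrand\n")
                for h in hits:
                    fh.write(f"{h.gene_id}\t{h.element_name}\t{h.category}\t"
                             f"{h.position}\t{h.strand}\n")
            outputs.append(out)
            if hits:
                per_elem, per_cat = annotation.summarize_elements(hits)
                out2 = outdir / "element_summary.tsv"
                with open(out2, "w") as fh:
                    fh.write("kind\tname\tpercent\n")
                    for name, pct in per_elem.items():
                        fh.write(f"element\t{name}\t{pct:.2f}\n")
                    for name, pct in per_cat.items():
                        fh.write(f"category\t{name}\t{pct:.2f}\n")
                outputs.append(out2)

        elif stage == "germination":
            records = dormancy.read_germination_table(
                _need(config, "germination_tsv", stage)
            )
            out = outdir / "germination_stats.tsv"
            with open(out, "w") as fh:
                fh.write("variety\treplicate\tn1\tn2\tn3\tN\tgi\tgr\n")
                for r in records:
                    fh.write(f"{r.variety}\t{r.replicate}\t{r.n1}\t{r.n2}\t"
                             f"{r.n3}\t{r.N}\t{r.gi:.4f}\t{r.gr:.2f}\n")
            outputs.append(out)

        elif stage == "expression":
            import pandas as pd

            values = pd.read_csv(
                _need(config, "expression_tsv", stage), sep="\t", index_col=0
            )
            meta = pd.read_csv(
                _need(config, "expression_meta_tsv", stage), sep="\t",
                index_col=0,
            )
            matrix = dormancy.ExpressionMatrix(values=values, metadata=meta)
            calls = dormancy.classify_candidates(matrix)
            out = outdir / "candidates.tsv"
            with open(out, "w") as fh:
                fh.write("gene_id\tdirection\n")
                for c in calls:
                    fh.write(f"{c.gene_id}\t{c.direction}\n")
            outputs.append(out)

        elapsed = time.perf_counter() - t0
        logger.info("stage %-11s %6.2fs  %s", stage, elapsed,
                    ", ".join(p.name for p in outputs))
        manifest["stages"][stage] = {
            "outputs": {
                p.name: {"sha256": _sha256(p), "rows": _rows(p)}
                for p in outputs
            }
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _codon_align_pair(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon alignment of two CDSs via their protein global alignment."""
    from .core_io import SequenceSet

    prot = SequenceSet(
        {"a": translate_cds(cds_a, permissive=True),
         "b": translate_cds(cds_b, permissive=True)},
        "protein",
    )
    aln = phylo.progressive_align(prot)
    codon = evolution.back_translate(aln, SequenceSet({"a": cds_a, "b": cds_b}))
    rows = dict(codon.rows)
    return rows["a"], rows["b"]


# ---------------------------------------------------------------------------
# bundled synthetic demo run
# ---------------------------------------------------------------------------

def write_demo_inputs(directory: str | Path, seed: int = 0) -> RunConfig:
    """Generate a small synthetic input set covering every stage and return
    a config that runs the full pipeline on it."""
    from . import synthetic
    from .core_io import GeneRecord, write_gene_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    proteins, _ = synthetic.simulate_proteome(6, 4, (60, 120), seed=seed)
    write_fasta(proteins, directory / "proteins.fasta")

    # three duplicated CDS pairs (tight paralogs) plus unrelated decoys
    cds_records: dict[str, str] = {}
    rng_pairs = [(0.05, 0.01), (0.1, 0.02), (0.2, 0.05)]
    for k, (ks, ka) in enumerate(rng_pairs):
        a, b, _ = synthetic.evolve_codon_pair(80, ks, ka, seed=seed + k)
        cds_records[f"Ta|gene{2 * k + 1}"] = "ATG" + a
        cds_records[f"Ta|gene{2 * k + 2}"] = "ATG" + b
    for k in range(2):
        decoy, _, _ = synthetic.evolve_codon_pair(80, 0.0, 0.0, seed=seed + 50 + k)
        cds_records[f"Os|decoy{k + 1}"] = "ATG" + decoy
    write_fasta(cds_records, directory / "cds.fasta")

    genes = [
        GeneRecord(gene_id=f"gene{i + 1}", chromosome="1A",
                   start=100_000 + i * 40_000, end=101_000 + i * 40_000,
                   orf_length=300, protein_length=99, mw=11000.0, pi=7.0)
        for i in range(6)
    ]
    write_gene_table(genes, directory / "genes.tsv")

    promoters, _ = synthetic.simulate_promoters(
        4, {"ABRE": 6, "MBS": 3, "LTR": 2}, length=600, seed=seed
    )
    write_fasta(promoters, directory / "promoters.fasta")

    germination, _ = synthetic.simulate_germination(
        synthetic.DEFAULT_VARIETIES, seed=seed
    )
    with open(directory / "germination.tsv", "w") as fh:
        fh.write("variety\treplicate\tn1\tn2\tn3\tN\n")
        for r in germination:
            fh.write(f"{r.variety}\t{r.replicate}\t{r.n1}\t{r.n2}\t{r.n3}\t{r.N}\n")

    matrix, _ = synthetic.simulate_expression(n_genes=30, n_low_direction=5,
                                              n_high_direction=3, seed=seed)
    matrix.values.to_csv(directory / "expression.tsv", sep="\t")
    matrix.metadata.to_csv(directory / "expression_meta.tsv", sep="\t")

    return RunConfig(
        output_dir=str(directory / "out"),
        seed=seed,
        stages={s: True for s in STAGE_ORDER},
        inputs={
            "proteins_fasta": str(directory / "proteins.fasta"),
            "cds_fasta": str(directory / "cds.fasta"),
            "gene_table": str(directory / "genes.tsv"),
            "promoters_fasta": str(directory / "promoters.fasta"),
            "germination_tsv": str(directory / "germination.tsv"),
            "expression_tsv": str(directory / "expression.tsv"),
            "expression_meta_tsv": str(directory / "expression_meta.tsv"),
        },
        params={"bootstrap": 20},
    )
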