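"""End-to-end orchestration: one config, one reproducible report bundle.

Thresholds default to the study's stated parameters: aligned length
> 300 bp and identity >= 40% for paralogy, reciprocal best hit for
orthology, sliding window 150 bp / step 9 bp, synonymous clock
lambda = 6.5e-9 per site per year, bootstrap 1000, species divergence
reference 12 My.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import census as census_mod
from . import expression, homology, phylogeny, promoter, selection, seqio

log = logging.getLogger("famevol")

DEFAULT_THRESHOLDS = {
    "aligned_bp": 300,
    "identity": 0.40,
    "window_bp": 150,
    "step_bp": 9,
    "lambda_syn_per_year": 6.5e-9,
    "bootstrap_reps": 1000,
    "species_divergence_my": 12.0,
    "promoter_window_bp": 2000,
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    seed: int
    outdir: str
    cds_fasta: str | None = None
    gene_models: str | None = None
    msa_fasta: str | None = None
    anchors_tsv: str | None = None
    promoters_fasta: str | None = None
    ct_tsv: str | None = None
    reference_gene: str = "TIP41"
    calibrator: str = "0h"
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = dict(DEFAULT_THRESHOLDS, **raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def manifest(self) -> dict:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return {"config": asdict(self),
                "config_sha256": hashlib.sha256(blob).hexdigest()}


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every configured stage and write the TSV report bundle.

    Stages with no configured inputs are skipped; any stage failure aborts
    with the stage name.  Returns the mapping of report names to paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("cds_fasta", "gene_models", "msa_fasta", "anchors_tsv",
                "promoters_fasta", "ct_tsv"):
        val = getattr(config, key)
        if val is not None and not Path(val).exists():
            raise PipelineError(f"missing input file for {key}: {val}")
    outputs: dict[str, Path] = {}
    thr = config.thresholds

    cds = (seqio.read_fasta(config.cds_fasta)
           if config.cds_fasta else None)

    if cds is not None and config.gene_models:
        models = seqio.read_gene_models(config.gene_models, cds)
        proteins = [census_mod.ProteinRecord(m.gene_id,
                                             census_mod.translate_orf(m.cds_seq))
                    for m in models]
        report = _stage("census")(census_mod.census)(models, proteins)
        path = outdir / "census.tsv"
        df = report.to_frame()
        with open(path, "w") as fh:
            fh.write("# columns: gene_id, orf_len, aa_len, mw, pi, exon_count\n")
            df.to_csv(fh, sep="\t", index=False)
            fh.write("# summary: " + json.dumps(report.summary) + "\n")
        outputs["census"] = path

    pairs = None
    if cds is not None and len(cds) >= 2:
        pairs = _stage("homologs")(homology.find_paralogs)(
            cds, aligned_bp_min=thr["aligned_bp"],
            identity_min=thr["identity"])
        path = outdir / "pairs.tsv"
        homology.write_pairs(pairs, path)
        outputs["pairs"] = path

    if pairs:
        rows = []
        tracks = []
        for p in pairs:
            aln = selection.codon_align(p.id_a, cds[p.id_a], p.id_b, cds[p.id_b])
            res = _stage("kaks")(selection.kaks_ng86)(aln)
            if res.ka is not None and res.ks is not None:
                rows.append((f"{p.id_a}-{p.id_b}", res.ka, res.ks))
            for s, e, r in selection.sliding_window(
                    aln, thr["window_bp"], thr["step_bp"]):
                tracks.append((f"{p.id_a}-{p.id_b}", s, e,
                               "" if r is None else round(r, 4)))
        if rows:
            rep = selection.selection_report(
                rows, lam=thr["lambda_syn_per_year"],
                recent_my=thr["species_divergence_my"])
            path = outdir / "table_selection.tsv"
            with open(path, "w") as fh:
                fh.write("# columns: pair, ka, ks, kaks, t_my, "
                         "selection_class, group\n")
                rep["table"].to_csv(fh, sep="\t", index=False)
            outputs["selection"] = path
            path = outdir / "windows.tsv"
            pd.DataFrame(tracks, columns=["pair", "start_bp", "end_bp", "kaks"]
                         ).to_csv(path, sep="\t", index=False)
            outputs["windows"] = path

    if config.msa_fasta:
        msa = seqio.read_fasta(config.msa_fasta, seqio.PROTEIN).records
        tree = _stage("tree")(phylogeny.bootstrap_support)(
            msa, n_reps=thr["bootstrap_reps"], seed=config.seed)
        path = outdir / "tree.nwk"
        seqio.write_newick(tree, path)
        outputs["tree"] = path
        if config.anchors_tsv:
            anchors = dict(pd.read_csv(config.anchors_tsv, sep="\t",
                                       comment="#").values)
            assign = _stage("subfamilies")(phylogeny.assign_subfamilies)(
                tree, anchors)
            path = outdir / "subfamilies.tsv"
            pd.DataFrame(sorted(assign.assignments.items()),
                         columns=["gene", "subfamily"]
                         ).to_csv(path, sep="\t", index=False)
            outputs["subfamilies"] = path

    if config.promoters_fasta:
        proms = seqio.read_fasta(config.promoters_fasta)
        dictionary = promoter.ElementDictionary.packaged()
        hits = _stage("cis")(promoter.scan_elements)(proms, dictionary)
        path = outdir / "cis_hits.tsv"
        promoter.write_hits(hits, path)
        outputs["cis_hits"] = path
        summary = promoter.summarize_elements(hits, dictionary)
        path = outdir / "cis_summary.tsv"
        with open(path, "w") as fh:
            fh.write("# columns: element, category, subcategory, count, "
                     "category_share_pct\n")
            fh.write("element\tcategory\tsubcategory\tcount\tcategory_share_pct\n")
            for name, (iupac, cat, sub) in dictionary.entries.items():
                fh.write(f"{name}\t{cat}\t{sub}\t{summary.counts[name]}\t"
                         f"{summary.element_share[name]:.2f}\n")
        outputs["cis_summary"] = path

    if config.ct_tsv:
        ct = pd.read_csv(config.ct_tsv, sep="\t", comment="#")
        folds = _stage("qpcr")(expression.ddct)(
            ct, config.reference_gene, config.calibrator)
        path = outdir / "folds.tsv"
        folds.to_csv(path, sep="\t", index=False)
        outputs["folds"] = path

    manifest = config.manifest()
    manifest["outputs"] = {k: str(v) for k, v in outputs.items()}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    outputs["manifest"] = outdir / "run_manifest.json"
    return outputs
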