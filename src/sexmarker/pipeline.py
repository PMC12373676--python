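"""End-to-end marker-discovery pipeline and machine-readable reports.

Stage order: k-mer sieve -> expression filters -> gametolog pairing ->
CAPS design -> in-silico assay validation. Any stage can be skipped by
supplying its output directly; per-stage survivor counts and the full
configuration are written into the summary for provenance.
"""

from __future__ import annotations

import json
import logging
import time
from math import comb
from dataclasses import asdict
from pathlib import Path
from typing import Any, Sequence

from . import assay, design, expression, kmer, pairing
from .core import (
    ExpressionTable,
    FilterConfig,
    Genotype,
    RestrictionEnzyme,
    SeqRecord,
    Sex,
    read_enzyme_table,
    read_fasta,
    write_fasta,
)

log = logging.getLogger("sexmarker")

EXIT_OK = 0
EXIT_NO_CANDIDATES = 3
EXIT_INPUT_ERROR = 4


class ConfigError(ValueError):
    """Pipeline configuration is inconsistent or incomplete."""


def candidate_to_dict(c: design.CapsCandidate) -> dict[str, Any]:
    return {
        "enzyme": {"name": c.site.enzyme.name,
                   "recognition": c.site.enzyme.recognition,
                   "cut_offset": c.site.enzyme.cut_offset},
        "site": {"allele": c.site.allele_with_site,
                 "site_start": c.site.site_start,
                 "alignment_column": c.site.alignment_column,
                 "strand": c.site.strand},
        "fwd": c.fwd.seq, "rev": c.rev.seq,
        "fwd_degeneracy": c.fwd.degeneracy, "rev_degeneracy": c.rev.degeneracy,
        "amplicon_len_x": c.amplicon_len_x, "amplicon_len_y": c.amplicon_len_y,
        "bands": {g.value: list(p.bands) for g, p in c.predicted_bands.items()},
        "probes": None if c.probes is None else {
            "cut_allele": c.probes.probe_for_cut_allele,
            "uncut_allele": c.probes.probe_for_uncut_allele,
        },
        "diagnostic": c.diagnostic,
        "score": c.score,
    }


def default_enzyme_table() -> list[RestrictionEnzyme]:
    from .fixtures import enzyme_table_path
    return read_enzyme_table(enzyme_table_path())


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run every configured stage and write reports into ``outdir``.

    Required config keys: ``males``/``females`` (per-sample FASTA paths),
    ``transcripts`` (candidate transcript FASTA), ``expr`` + ``sexes``
    (TPM table and sex labels), ``x_loci`` (X-locus FASTA). Optional:
    ``enzymes`` (TSV; packaged table by default), plus any FilterConfig
    or PairingPolicy field.

    Returns the summary dict (also written to summary.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for key in ("males", "females", "transcripts", "expr", "sexes", "x_loci"):
        if key not in config:
            raise ConfigError(f"missing config key: {key}")
    if not config["males"] or not config["females"]:
        raise ConfigError("need at least one sample FASTA per sex")

    cfg = FilterConfig(**{k: config[k] for k in
                          ("k", "min_male_mean_tpm", "max_female_tpm",
                           "min_log2fc", "max_fdr", "pseudocount")
                          if k in config})
    policy = pairing.PairingPolicy(**{k: config[k] for k in
                                      ("min_identity", "min_coverage",
                                       "max_secondary_ratio") if k in config})
    enzymes = (read_enzyme_table(config["enzymes"]) if "enzymes" in config
               else default_enzyme_table())
    summary: dict[str, Any] = {"config": {**config,
                                          "filter": asdict(cfg),
                                          "pairing": asdict(policy)},
                               "stages": {}}

    def stage(name: str, n_in: int, n_out: int, t0: float) -> None:
        summary["stages"][name] = {"n_in": n_in, "n_out": n_out,
                                   "seconds": round(time.perf_counter() - t0, 3)}
        log.info("%s: %d -> %d (%.2fs)", name, n_in, n_out,
                 time.perf_counter() - t0)

    # stage 1: k-mer sieve ---------------------------------------------------
    t0 = time.perf_counter()
    transcripts = read_fasta(config["transcripts"])
    profiles = []
    for sex, paths in ((Sex.male, config["males"]), (Sex.female, config["females"])):
        for p in paths:
            profiles.append(kmer.build_profile(read_fasta(p), cfg.k, sex,
                                               sample_id=Path(p).stem))
    specific = kmer.male_specific_kmers(profiles)
    hits = kmer.sieve_transcripts(transcripts, specific, cfg.k)
    with open(outdir / "sieve.tsv", "w") as fh:
        fh.write("transcript_id\tn_specific_kmers\n")
        for h in hits:
            fh.write(f"{h.transcript_id}\t{h.n_specific_kmers}\n")
    sieve_ids = [h.transcript_id for h in hits]
    stage("sieve", len(transcripts), len(sieve_ids), t0)

    # stage 2: expression filters --------------------------------------------
    t0 = time.perf_counter()
    expr = ExpressionTable.from_tsv(config["expr"], config["sexes"])
    bias = expression.male_bias_test(expr, cfg)
    strict = set(expression.strict_tpm_filter(expr, cfg))
    # The rank-sum test has a hard p-value floor of 2/C(n, n_male); when
    # that floor exceeds the FDR threshold the test cannot discriminate
    # at these sample sizes, so the gate falls back to log2FC alone
    # (p and FDR are still reported).
    n_m = len(expr.columns_for(Sex.male))
    n_f = len(expr.columns_for(Sex.female))
    powered = (n_m >= 2 and n_f >= 2
               and 2.0 / comb(n_m + n_f, n_m) <= cfg.max_fdr)
    summary["bias_test_powered"] = bool(powered)
    if powered:
        biased = set(bias.loc[bias["passed"], "transcript"])
    else:
        biased = set(bias.loc[bias["log2fc"] >= cfg.min_log2fc, "transcript"])
    bias.to_csv(outdir / "filter.tsv", sep="\t", index=False)
    survivors = [t for t in sieve_ids if t in strict and t in biased]
    stage("filter", len(sieve_ids), len(survivors), t0)

    # stage 3: gametolog pairing ---------------------------------------------
    t0 = time.perf_counter()
    x_loci = {r.id: r.seq for r in read_fasta(config["x_loci"])}
    seq_by_id = {r.id: r.seq for r in transcripts}
    pairs = [pairing.find_counterpart(t, seq_by_id[t], x_loci, policy)
             for t in survivors]
    accepted = [p for p in pairs if p.status == pairing.PairStatus.accepted]
    ranked_pairs = pairing.divergence_rank(accepted)
    with open(outdir / "pairs.tsv", "w") as fh:
        fh.write("y_id\tx_id\tstatus\tdivergence\n")
        for p in pairs:
            fh.write(f"{p.y_id}\t{p.x_id or '.'}\t{p.status.value}\t"
                     f"{'' if p.divergence is None else f'{p.divergence:.4f}'}\n")
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for p in ranked_pairs:
        write_fasta([SeqRecord(p.x_id, p.alignment.x_row),
                     SeqRecord(p.y_id, p.alignment.y_row)],
                    aln_dir / f"{p.y_id}.aln.fasta")
    stage("pair", len(survivors), len(ranked_pairs), t0)

    # stage 4: CAPS design ---------------------------------------------------
    t0 = time.perf_counter()
    candidates: list[design.CapsCandidate] = []
    cand_src: list[str] = []
    for p in ranked_pairs:
        for site in design.scan_differential_sites(p.alignment, enzymes):
            try:
                cand = design.build_candidate(p.alignment, site)
            except design.DesignFailure as exc:
                log.debug("site %s@%d on %s skipped: %s", site.enzyme.name,
                          site.alignment_column, p.y_id, exc)
                continue
            candidates.append(cand)
            cand_src.append(p.y_id)
    order = design.rank_candidates(candidates)
    src_by_id = {id(c): s for c, s in zip(candidates, cand_src)}
    stage("design", len(ranked_pairs), len(order), t0)

    # stage 5: in-silico validation ------------------------------------------
    t0 = time.perf_counter()
    reports = []
    for c in order:
        ok = (c.diagnostic
              and assay.call_genotype(c.predicted_bands[Genotype.XX].bands,
                                      c.predicted_bands, 0) == Genotype.XX
              and assay.call_genotype(c.predicted_bands[Genotype.XY].bands,
                                      c.predicted_bands, 0) == Genotype.XY)
        d = candidate_to_dict(c)
        d["transcript"] = src_by_id[id(c)]
        d["validated"] = ok
        reports.append(d)
    valid = [r for r in reports if r["validated"]]
    with open(outdir / "candidates.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    stage("insilico", len(order), len(valid), t0)

    summary["n_candidates"] = len(valid)
    summary["top_candidate"] = valid[0] if valid else None
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def genotype_samples(templates: Sequence[SeqRecord], candidate: dict[str, Any],
                     tolerance_bp: int = 10) -> list[dict[str, Any]]:
    """Run one designed assay over sample templates: PCR, digestion and
    genotype call per record."""
    enzyme = RestrictionEnzyme(**candidate["enzyme"])
    patterns = {Genotype.XX: assay.BandPattern(tuple(candidate["bands"]["XX"])),
                Genotype.XY: assay.BandPattern(tuple(candidate["bands"]["XY"]))}
    out = []
    for rec in templates:
        amps = assay.insilico_pcr(rec.seq, candidate["fwd"], candidate["rev"])
        bands: list[int] = []
        for a in amps:
            bands.extend(assay.digest(a, enzyme).bands)
        call = (assay.call_genotype(bands, patterns, tolerance_bp).value
                if bands else "no_product")
        out.append({"sample_id": rec.id, "bands": sorted(bands), "call": call})
    return out
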