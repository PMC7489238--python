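"""End-to-end runners for the two component tools.

``run_protein_motif_finder`` chains motif discovery, scoring, the protein
x motif matrices, the heatmap filter pipeline, Ward clustering and the
C-index scan, writing TSV tables to a results directory.

``run_sequence_properties_analyzer`` chains residue enrichment, biased
regions and counts, the bias-index bootstrap test, low-complexity
segmentation, disorder scoring, the two rank-sum comparisons and charge
clusters, again as TSV plus plain-text summaries.

Tabular TSVs are the canonical interface: headers are fixed, column order
is stable, and a rerun with identical configuration and seed is
byte-identical.  ``run_metadata.json`` records every parameter, the seed
and input digests so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .bias import (
    bias_significance,
    count_biased_proteins,
    find_biased_regions,
    residue_log_enrichment,
)
from .charge import cluster_proportions, find_charge_clusters
from .cluster import (
    apply_heatmap_filters,
    build_motif_matrix,
    c_index_scan,
    dcor_distance_matrix,
    ward_clusters,
)
from .complexity import (
    disorder_scores,
    external_predictor,
    percent_disordered,
    percent_low_complexity,
    propensity_disorder_scores,
    ranksum_test,
    read_external_scores,
    seg_segments,
)
from .motifs import run_motif_finder
from .seqio import AA_ORDER, SequenceSet, read_fasta, residue_frequencies

logger = logging.getLogger("promin")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[promin] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """All knobs of a run; every field is recorded in run_metadata.json."""

    foreground: str | Path = ""
    background: str | Path = ""
    out: str | Path = "promin_results"
    width: int = 7
    p_thresh: float = 1e-6
    min_occ: int = 5
    bias_p: float = 1e-20  # filter-1 biased-region threshold
    dcor_min: float = 0.65
    top_motifs: int = 70
    n_samples: int = 1000  # bootstrap samples for the bias test
    seg_window: int = 12
    seg_trigger: float = 2.2
    seg_extension: float = 2.5
    charge_window: int = 30
    charge_alpha: float = 1e-3
    region_min_len: int = 5
    region_p: float = 1e-3  # reporting threshold for biased regions
    cluster_k: int = 8
    seed: int = 0
    threads: int = 1
    disorder_scores_path: str | None = None

    def validate(self) -> None:
        checks = [
            self.width % 2 == 1 and 3 <= self.width <= 35,
            0 < self.p_thresh <= 1,
            self.min_occ >= 1,
            0 < self.bias_p <= 1,
            0 <= self.dcor_min <= 1,
            self.top_motifs >= 1,
            self.n_samples >= 1,
            self.seg_window >= 2,
            self.seg_trigger >= 0 and self.seg_extension >= self.seg_trigger,
            self.charge_window >= 2,
            0 < self.charge_alpha <= 1,
            self.region_min_len >= 5,
            0 < self.region_p <= 1,
            self.cluster_k >= 2,
            self.threads >= 1,
        ]
        if not all(checks):
            raise ValueError("RunConfig contains out-of-range parameters")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _write_metadata(config: RunConfig, out: Path, tool: str) -> None:
    meta = {
        "tool": tool,
        "version": __version__,
        "parameters": {k: (str(v) if isinstance(v, Path) else v)
                       for k, v in asdict(config).items()},
        "input_digests": {
            "foreground": _sha256(config.foreground),
            "background": _sha256(config.background),
        },
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def _load_sets(config: RunConfig) -> tuple[SequenceSet, SequenceSet]:
    fg = read_fasta(config.foreground, name="foreground")
    bg = read_fasta(config.background, name="background")
    logger.info(
        "loaded foreground %d sequences (%d residues), background %d (%d residues)",
        len(fg), fg.total_residues, len(bg), bg.total_residues,
    )
    return fg, bg


def run_protein_motif_finder(config: RunConfig) -> Path:
    """Motif discovery, scoring, heatmap filtering, clustering, C-index."""
    config.validate()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    fg, bg = _load_sets(config)

    stats = run_motif_finder(
        fg, bg, width=config.width, p_thresh=config.p_thresh, min_occ=config.min_occ
    )
    logger.info(
        "motif discovery: width=%d p<%g min_occ=%d -> %d motifs",
        config.width, config.p_thresh, config.min_occ, len(stats),
    )
    rows = [
        {
            "motif": s.motif.pattern,
            "fg_occurrences": s.fg_occurrences,
            "bg_occurrences": s.bg_occurrences,
            "fg_proteins": s.fg_proteins,
            "bg_proteins": s.bg_proteins,
            "enrichment_density": s.enrichment,
            "enrichment_protein_fraction": s.enrichment_protein_fraction,
            "ps_value": s.ps_value if s.ps_value is not None else "",
            "infinite_flag": int(s.infinite),
        }
        for s in stats
    ]
    cols = ["motif", "fg_occurrences", "bg_occurrences", "fg_proteins",
            "bg_proteins", "enrichment_density", "enrichment_protein_fraction",
            "ps_value", "infinite_flag"]
    _write_tsv(pd.DataFrame(rows, columns=cols), out / "motif_stats.tsv")
    wc = pd.DataFrame(
        [
            {
                "motif": s.motif.pattern,
                "size_protein_count": s.fg_proteins,
                "size_enrichment": s.enrichment,
                "size_ps": s.ps_value if s.ps_value is not None else "",
            }
            for s in stats
        ],
        columns=["motif", "size_protein_count", "size_enrichment", "size_ps"],
    )
    _write_tsv(wc, out / "wordcloud_sizes.tsv")

    if not stats:
        logger.info("no enriched motifs found; writing empty tables")
    bg_freq = residue_frequencies(bg)
    biased_ids = {
        seq.id
        for seq in fg
        if find_biased_regions(
            seq, bg_freq, min_len=config.region_min_len, p_report=config.bias_p
        )
    }
    logger.info("filter 1: %d/%d foreground proteins carry a biased region "
                "(p < %g)", len(biased_ids), len(fg), config.bias_p)
    matrix = build_motif_matrix(fg, stats, bg)

    prov_rows = []
    heat1 = None
    for hm in (1, 2, 3):
        filtered, prov = apply_heatmap_filters(
            matrix,
            stats,
            biased_ids,
            heatmap=hm,
            dcor_min=config.dcor_min,
            top_motifs=config.top_motifs,
            poi_size=len(fg),
        )
        layer = filtered.counts if hm == 3 else filtered.enrichment
        df = pd.DataFrame(layer, columns=filtered.motifs)
        df.insert(0, "protein_id", filtered.protein_ids)
        _write_tsv(df, out / f"heatmap{hm}.tsv")
        prov_rows.extend(
            {"heatmap": hm, "filter": f, "axis": a, "name": n}
            for f, a, n in prov.dropped
        )
        prov_rows.extend(
            {"heatmap": hm, "filter": "note", "axis": "", "name": note}
            for note in prov.notes
        )
        if hm == 1:
            heat1 = filtered
        logger.info("heatmap %d: %d proteins x %d motifs survive filters",
                    hm, len(filtered.protein_ids), len(filtered.motifs))
    _write_tsv(
        pd.DataFrame(prov_rows, columns=["heatmap", "filter", "axis", "name"]),
        out / "filter_provenance.tsv",
    )

    clusters = pd.DataFrame(columns=["protein_id", "cluster_label"])
    cindex = pd.DataFrame(columns=["k", "c_index"])
    n1 = len(heat1.protein_ids)
    if n1 >= 3 and len(heat1.motifs) >= 1:
        D = dcor_distance_matrix(heat1.enrichment)
        k = min(config.cluster_k, n1)
        labels = ward_clusters(D, k)
        clusters = pd.DataFrame(
            {"protein_id": heat1.protein_ids, "cluster_label": labels}
        )
        scan = c_index_scan(D, range(2, min(50, n1 - 1) + 1))
        cindex = pd.DataFrame(scan, columns=["k", "c_index"])
        logger.info("clustering: %d proteins cut at k=%d", n1, k)
    else:
        logger.info("clustering skipped: fewer than 3 proteins after filtering")
    _write_tsv(clusters, out / "clusters.tsv")
    _write_tsv(cindex, out / "cindex.tsv")

    _write_metadata(config, out, "protein-motif-finder")
    return out


def run_sequence_properties_analyzer(config: RunConfig) -> Path:
    """Residue bias, BI test, LCR/disorder rank-sums and charge clusters."""
    config.validate()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    fg, bg = _load_sets(config)
    fg_freq = residue_frequencies(fg)
    bg_freq = residue_frequencies(bg)

    log_enr = residue_log_enrichment(fg_freq, bg_freq)
    _write_tsv(
        pd.DataFrame(
            {
                "residue": list(AA_ORDER),
                "fg_freq": fg_freq.values,
                "bg_freq": bg_freq.values,
                "log2_enrichment": log_enr,
            }
        ),
        out / "aa_enrichment.tsv",
    )

    regions = []
    for seq in fg:
        regions.extend(
            find_biased_regions(
                seq, bg_freq, min_len=config.region_min_len, p_report=config.region_p
            )
        )
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "protein_id": r.protein_id,
                    "residue": r.residue,
                    "start": r.start,
                    "end": r.end,
                    "count": r.count,
                    "p": r.p,
                }
                for r in regions
            ],
            columns=["protein_id", "residue", "start", "end", "count", "p"],
        ),
        out / "biased_regions.tsv",
    )
    counts = count_biased_proteins(
        fg, bg_freq, p_thresh=config.region_p, min_len=config.region_min_len
    )
    _write_tsv(
        pd.DataFrame(
            {"residue": list(AA_ORDER), "n_proteins": [counts[a] for a in AA_ORDER]}
        ),
        out / "biased_protein_counts.tsv",
    )
    logger.info("biased regions: %d regions across %d foreground proteins",
                len(regions), len(fg))

    bi = bias_significance(fg, bg, n_samples=config.n_samples, seed=config.seed)
    (out / "bias_test.txt").write_text(
        f"observed_bi\t{bi.observed_bi:.6f}\n"
        f"n_samples\t{bi.n_samples}\n"
        f"seed\t{bi.seed}\n"
        f"p\t{bi.p:.6g}\n"
    )
    logger.info("bias index %.4f, bootstrap p = %.4g", bi.observed_bi, bi.p)

    predictor = None
    predictor_name = "topidp-window21"
    if config.disorder_scores_path:
        predictor = external_predictor(read_external_scores(config.disorder_scores_path))
        predictor_name = f"external:{config.disorder_scores_path}"

    def _properties(seq):
        segs = seg_segments(
            seq, config.seg_window, config.seg_trigger, config.seg_extension
        )
        lcr_res = sum(s.end - s.start + 1 for s in segs)
        scores = disorder_scores(seq, predictor)
        return (
            lcr_res,
            percent_low_complexity(seq, segs),
            int((np.asarray(scores) >= 0.5).sum()),
            percent_disordered(scores),
        )

    results = {}
    for label, sset in (("foreground", fg), ("background", bg)):
        if config.threads > 1:
            props = Parallel(n_jobs=config.threads)(
                delayed(_properties)(seq) for seq in sset
            )
        else:
            props = [_properties(seq) for seq in sset]
        results[label] = props

    comp_rows, dis_rows = [], []
    pct_lcr, pct_dis = {}, {}
    for label, sset in (("foreground", fg), ("background", bg)):
        pct_lcr[label] = [p[1] for p in results[label]]
        pct_dis[label] = [p[3] for p in results[label]]
        for seq, (lcr_res, lcr_pct, dis_res, dis_pct) in zip(sset, results[label]):
            comp_rows.append(
                {"protein_id": seq.id, "set": label, "length": seq.length,
                 "lcr_residues": lcr_res, "percent_lcr": lcr_pct}
            )
            dis_rows.append(
                {"protein_id": seq.id, "set": label, "length": seq.length,
                 "disordered_residues": dis_res, "percent_disordered": dis_pct,
                 "predictor": predictor_name}
            )
    _write_tsv(pd.DataFrame(comp_rows), out / "complexity.tsv")
    _write_tsv(pd.DataFrame(dis_rows), out / "disorder.tsv")

    lcr_test = ranksum_test(pct_lcr["foreground"], pct_lcr["background"])
    dis_test = ranksum_test(pct_dis["foreground"], pct_dis["background"])
    (out / "property_tests.txt").write_text(
        "property\tstatistic\tp\tn_fg\tn_bg\n"
        f"percent_lcr\t{lcr_test.statistic:.1f}\t{lcr_test.p:.6g}\t"
        f"{lcr_test.n_fg}\t{lcr_test.n_bg}\n"
        f"percent_disordered\t{dis_test.statistic:.1f}\t{dis_test.p:.6g}\t"
        f"{dis_test.n_fg}\t{dis_test.n_bg}\n"
    )
    logger.info("rank-sum p: LCR %.4g, disorder %.4g", lcr_test.p, dis_test.p)

    charge_rows = []
    for label, sset in (("foreground", fg), ("background", bg)):
        for seq in sset:
            for c in find_charge_clusters(
                seq, bg_freq, window=config.charge_window, alpha=config.charge_alpha
            ):
                charge_rows.append(
                    {"protein_id": c.protein_id, "set": label, "sign": c.sign,
                     "start": c.start, "end": c.end,
                     "charged_count": c.charged_count, "p": c.p}
                )
    _write_tsv(
        pd.DataFrame(
            charge_rows,
            columns=["protein_id", "set", "sign", "start", "end",
                     "charged_count", "p"],
        ),
        out / "charge_clusters.tsv",
    )
    props = cluster_proportions(
        fg, bg, window=config.charge_window, alpha=config.charge_alpha,
        bg_freq=bg_freq,
    )

    (out / "summary.txt").write_text(
        f"bias_index\t{bi.observed_bi:.6f}\n"
        f"bias_p\t{bi.p:.6g}\n"
        f"lcr_ranksum_p\t{lcr_test.p:.6g}\n"
        f"disorder_ranksum_p\t{dis_test.p:.6g}\n"
        f"charge_positive_foreground\t{props[('foreground', 'positive')]:.4f}\n"
        f"charge_positive_background\t{props[('background', 'positive')]:.4f}\n"
        f"charge_negative_foreground\t{props[('foreground', 'negative')]:.4f}\n"
        f"charge_negative_background\t{props[('background', 'negative')]:.4f}\n"
    )
    _write_metadata(config, out, "sequence-properties-analyzer")
    return out
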