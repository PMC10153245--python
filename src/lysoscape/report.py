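"""Roll-up reports: cohort summaries, recovery scoring against ground
truth, per-phylum density exports (with tree-annotation output), country x
phylum sampling matrices, and GFF3/TSV region writers."""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Phylo

from .detect import ProphageRegion

__all__ = [
    "regions_to_frame",
    "write_gff3",
    "match_regions",
    "cohort_summary",
    "phylum_density_export",
    "country_phylum_matrix",
]


def regions_to_frame(accession: str, regions: list[ProphageRegion]) -> pd.DataFrame:
    """Tabulate detector output for one genome."""
    rows = []
    for r in regions:
        att = r.att_repeat
        rows.append(
            dict(
                accession=accession,
                contig_id=r.contig_id,
                start=r.start,
                end=r.end,
                n_genes=r.n_genes,
                att_left=att[0] if att else -1,
                att_right=att[1] if att else -1,
                att_len=att[2] if att else 0,
                phage_annotated_genes=r.phage_annotated_genes,
                verified_bp_fraction=r.verified_bp_fraction,
                status=r.status,
                discard_reason=r.discard_reason or "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "contig_id", "start", "end", "n_genes", "att_left",
            "att_right", "att_len", "phage_annotated_genes",
            "verified_bp_fraction", "status", "discard_reason",
        ],
    )


def write_gff3(accession: str, regions: list[ProphageRegion], path) -> None:
    """Write regions as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for i, r in enumerate(regions, 1):
        attrs = [
            f"ID=prophage_{accession}_{i}",
            f"n_genes={r.n_genes}",
            f"verified_bp_fraction={r.verified_bp_fraction:.4f}",
            f"status={r.status}",
        ]
        if r.att_repeat:
            attrs.append(f"att_left={r.att_repeat[0] + 1}")
            attrs.append(f"att_right={r.att_repeat[1] + 1}")
            attrs.append(f"att_len={r.att_repeat[2]}")
        if r.discard_reason:
            attrs.append(f"discard_reason={r.discard_reason}")
        lines.append(
            "\t".join(
                [
                    r.contig_id,
                    "lysoscape",
                    "prophage",
                    str(r.start + 1),
                    str(r.end),
                    ".",
                    "+",
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def match_regions(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    min_reciprocal: float = 0.5,
) -> dict:
    """Region-level sensitivity/precision at a reciprocal-overlap threshold.

    A predicted (kept) region matches a truth region when their overlap is
    at least ``min_reciprocal`` of *both* lengths.  Each truth region can be
    matched at most once (greedy, largest overlap first).
    """
    kept = predicted[predicted["status"] == "kept"] if len(predicted) else predicted
    pairs = []
    for pi, p in kept.iterrows():
        for ti, t in truth.iterrows():
            if p["accession"] != t["accession"] or p["contig_id"] != t["contig_id"]:
                continue
            ov = _overlap(p["start"], p["end"], t["start"], t["end"])
            if ov >= min_reciprocal * (p["end"] - p["start"]) and ov >= min_reciprocal * (
                t["end"] - t["start"]
            ):
                pairs.append((ov, pi, ti))
    pairs.sort(reverse=True)
    used_p, used_t = set(), set()
    matches = 0
    for _, pi, ti in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matches += 1
    n_pred = len(kept)
    n_truth = len(truth)
    return dict(
        n_predicted=n_pred,
        n_truth=n_truth,
        n_matched=matches,
        sensitivity=matches / n_truth if n_truth else np.nan,
        precision=matches / n_pred if n_pred else np.nan,
    )


def cohort_summary(
    summaries: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
) -> pd.Series:
    """Cohort-level counts, with recovery metrics when truth is supplied."""
    out = {
        "genomes_processed": len(summaries),
        "lysogens": int(summaries["is_lysogen"].sum()) if len(summaries) else 0,
        "total_prophages": int(summaries["n_prophages"].sum()) if len(summaries) else 0,
        "total_prophage_bp": int(summaries["prophage_bp"].sum()) if len(summaries) else 0,
        "mags": int(summaries["is_mag"].sum())
        if len(summaries) and "is_mag" in summaries
        else 0,
    }
    if regions is not None and truth is not None:
        m = match_regions(regions, truth)
        out["sensitivity"] = m["sensitivity"]
        out["precision"] = m["precision"]
    return pd.Series(out)


def phylum_density_export(
    summaries: pd.DataFrame,
    newick_in=None,
    newick_out=None,
    annotation_out=None,
) -> pd.DataFrame:
    """Per-phylum density statistics and optional tree annotation export.

    Returns a table of mean, sd, sd/mean and n per phylum.  When a Newick
    tree is supplied it is pruned to the observed phylum labels and written
    back; the annotation table (phylum -> mean density) is written as TSV
    consumable by external tree viewers.
    """
    df = summaries[summaries["phylum"].astype(str).str.len() > 0]
    per = (
        df.groupby("phylum")["density"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=0), n="count")
        .reset_index()
    )
    per["sd_over_mean"] = np.where(per["mean"] > 0, per["sd"] / per["mean"], np.nan)
    if annotation_out is not None:
        per[["phylum", "mean"]].rename(columns={"mean": "mean_density"}).to_csv(
            annotation_out, sep="\t", index=False
        )
    if newick_in is not None and newick_out is not None:
        tree = Phylo.read(str(newick_in), "newick")
        keep = set(per["phylum"])
        for leaf in [t for t in tree.get_terminals() if t.name not in keep]:
            tree.prune(leaf)
        with io.StringIO() as buf:
            Phylo.write(tree, buf, "newick")
            Path(newick_out).write_text(buf.getvalue())
    return per


def country_phylum_matrix(
    summaries: pd.DataFrame,
    top_phyla: int | None = None,
    top_countries: int | None = None,
) -> pd.DataFrame:
    """Genome counts per phylum x country, sorted by marginal totals.

    Genomes with a missing country are routed to an "unknown" column; rows
    require a phylum label.  Log-scaling is left to the consumer.
    """
    df = summaries[summaries["phylum"].astype(str).str.len() > 0].copy()
    if len(df) == 0:
        return pd.DataFrame()
    country = df["country"].astype(str).str.strip()
    df["country"] = np.where(country.str.len() > 0, country, "unknown")
    mat = pd.crosstab(df["phylum"], df["country"])
    mat = mat.loc[
        mat.sum(axis=1).sort_values(ascending=False).index,
        mat.sum(axis=0).sort_values(ascending=False).index,
    ]
    if top_phyla is not None:
        mat = mat.iloc[:top_phyla]
    if top_countries is not None:
        mat = mat.iloc[:, :top_countries]
    return mat
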