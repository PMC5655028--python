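"""Readers and writers binding the pipeline stages together.

Tabular formats are plain CSV/TSV via pandas; promoters are FASTA via
Biopython.  Expression input comes either long (gene_id, time_days,
replicate, value) or summarised (gene_id, time_days, mean, se, n).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import GAMMA_TRANSCRIPT, GeneParams
from .fitting import ExpressionSeries
from .motifs import MotifHit, PromoterRecord

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "read_expression_csv",
    "write_expression_csv",
    "read_fasta",
    "write_fasta",
    "write_hits_tsv",
    "write_provenance",
]


def read_gene_table(path) -> dict[str, GeneParams]:
    """Gene parameter CSV with columns gene_id, K_PIF[, gamma_per_day]."""
    df = pd.read_csv(path)
    required = {"gene_id", "K_PIF"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    genes = {}
    for _, row in df.iterrows():
        gamma = float(row["gamma_per_day"]) if "gamma_per_day" in df.columns else GAMMA_TRANSCRIPT
        genes[str(row["gene_id"])] = GeneParams(
            str(row["gene_id"]), float(row["K_PIF"]), gamma
        )
    return genes


def write_gene_table(genes: dict[str, GeneParams], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes.values()],
            "K_PIF": [g.K_PIF for g in genes.values()],
            "gamma_per_day": [g.gamma for g in genes.values()],
        }
    ).to_csv(path, index=False)


def _series_from_long(df: pd.DataFrame) -> list[ExpressionSeries]:
    out = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        wide = sub.pivot_table(
            index="time_days", columns="replicate", values="value", sort=True
        )
        if wide.isna().any().any():
            raise ValueError(f"ragged replicate table for gene {gene_id}")
        out.append(
            ExpressionSeries(
                gene_id=str(gene_id),
                times=wide.index.to_numpy(dtype=float),
                replicates=wide.to_numpy(dtype=float),
            )
        )
    return out


def _series_from_summary(df: pd.DataFrame) -> list[ExpressionSeries]:
    out = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        sub = sub.sort_values("time_days")
        out.append(
            ExpressionSeries(
                gene_id=str(gene_id),
                times=sub["time_days"].to_numpy(dtype=float),
                mean=sub["mean"].to_numpy(dtype=float),
                se=sub["se"].to_numpy(dtype=float) if "se" in sub.columns else None,
                n_replicates=sub["n"].to_numpy() if "n" in sub.columns else None,
            )
        )
    return out


def read_expression_csv(path) -> list[ExpressionSeries]:
    """Read long- or summary-format expression CSV (format auto-detected)."""
    df = pd.read_csv(path)
    if {"gene_id", "time_days", "replicate", "value"}.issubset(df.columns):
        return _series_from_long(df)
    if {"gene_id", "time_days", "mean"}.issubset(df.columns):
        return _series_from_summary(df)
    raise ValueError(
        f"{path}: expected columns (gene_id, time_days, replicate, value) "
        "or (gene_id, time_days, mean[, se, n])"
    )


def write_expression_csv(series_list: list[ExpressionSeries], path, summary: bool = False) -> None:
    rows = []
    if summary:
        for s in series_list:
            for i, t in enumerate(s.times):
                rows.append(
                    {
                        "gene_id": s.gene_id,
                        "time_days": t,
                        "mean": s.mean[i],
                        "se": s.se[i] if s.se is not None else "",
                        "n": int(s.n_replicates[i]) if s.n_replicates is not None else "",
                    }
                )
    else:
        for s in series_list:
            if s.replicates is None:
                raise ValueError(f"{s.gene_id}: no replicates to write in long format")
            for i, t in enumerate(s.times):
                for r in range(s.replicates.shape[1]):
                    rows.append(
                        {
                            "gene_id": s.gene_id,
                            "time_days": t,
                            "replicate": r + 1,
                            "value": s.replicates[i, r],
                        }
                    )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fasta(path) -> list[PromoterRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(PromoterRecord(rec.id, str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    return records


def write_fasta(records: list[PromoterRecord], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in records],
        str(path),
        "fasta",
    )


def write_hits_tsv(hits: list[MotifHit], path) -> None:
    pd.DataFrame(
        {
            "seq_id": [h.seq_id for h in hits],
            "motif": [h.motif_name for h in hits],
            "strand": [h.strand for h in hits],
            "offset": [h.offset for h in hits],
            "match": [h.matched_text for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)


def write_provenance(path, **blocks) -> None:
    """Provenance JSON: resolved parameters, seed, package version."""
    from . import __version__

    payload = {"phypif_version": __version__}
    payload.update(blocks)
    Path(path).write_text(json.dumps(payload, indent=1, default=str) + "\n")
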