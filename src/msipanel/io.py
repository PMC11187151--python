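"""File formats: FASTA in; BED6 + TSV locus catalogs; TSV tables; JSON models.

All tables are plain TSV read/written through pandas; the locus catalog is a
BED6 (0-based half-open, copies in the score column, "+" strand) plus a TSV
sidecar carrying unit, unit length, copy number and optional gene label.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .instability_calling import NormalBaseline
from .locus_scan import MicrosatelliteLocus
from .panel_selection import PanelModel
from .synthetic_cohort import CohortTruth

LOCUS_TSV_COLUMNS = ["locus_id", "unit", "unit_len", "copies", "gene_label"]


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_locus_catalog(
    loci: Sequence[MicrosatelliteLocus], bed_path: str | Path, tsv_path: str | Path
) -> None:
    with open(bed_path, "w") as bed:
        for l in loci:
            bed.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.locus_id}\t{l.copies}\t+\n")
    pd.DataFrame(
        [
            (l.locus_id, l.unit, l.unit_len, l.copies, l.gene_label or "")
            for l in loci
        ],
        columns=LOCUS_TSV_COLUMNS,
    ).to_csv(tsv_path, sep="\t", index=False)


def read_locus_catalog(bed_path: str | Path, tsv_path: str | Path) -> list[MicrosatelliteLocus]:
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "locus_id", "score", "strand"],
    )
    side = pd.read_csv(tsv_path, sep="\t", keep_default_na=False)
    merged = bed.merge(side, on="locus_id", validate="one_to_one")
    return [
        MicrosatelliteLocus(
            locus_id=r.locus_id, chrom=r.chrom, start=int(r.start), end=int(r.end),
            unit=r.unit, unit_len=int(r.unit_len), copies=int(r.copies),
            gene_label=r.gene_label or None,
        )
        for r in merged.itertuples(index=False)
    ]


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_panel(panel: PanelModel, path: str | Path) -> None:
    payload = {
        "locus_ids": panel.locus_ids,
        "min_unstable": panel.min_unstable,
        "train_sensitivity": panel.train_sensitivity,
        "train_specificity": panel.train_specificity,
        "constraint_met": panel.constraint_met,
        "selection_log": panel.selection_log,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_panel(path: str | Path) -> PanelModel:
    d = json.loads(Path(path).read_text())
    return PanelModel(
        locus_ids=list(d["locus_ids"]),
        min_unstable=int(d["min_unstable"]),
        train_sensitivity=float(d.get("train_sensitivity", float("nan"))),
        train_specificity=float(d.get("train_specificity", float("nan"))),
        constraint_met=bool(d.get("constraint_met", True)),
        selection_log=list(d.get("selection_log", [])),
    )


def write_baselines(baselines: Mapping[str, NormalBaseline], path: str | Path) -> None:
    payload = {
        lid: {
            "pooled_support": sorted(b.pooled_support),
            "n_normals": b.n_normals,
            "mean_novel_frac": b.mean_novel_frac,
            "sd_novel_frac": b.sd_novel_frac,
            "pooled_families": b.pooled_families,
        }
        for lid, b in baselines.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_baselines(path: str | Path) -> dict[str, NormalBaseline]:
    d = json.loads(Path(path).read_text())
    return {
        lid: NormalBaseline(
            locus_id=lid,
            pooled_support=set(v["pooled_support"]),
            n_normals=int(v["n_normals"]),
            mean_novel_frac=float(v["mean_novel_frac"]),
            sd_novel_frac=float(v["sd_novel_frac"]),
            pooled_families=int(v.get("pooled_families", 0)),
        )
        for lid, v in d.items()
    }


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    payload = {
        "informative_locus_ids": sorted(truth.informative_locus_ids),
        "polymorphic_locus_ids": sorted(truth.polymorphic_locus_ids),
        "somatic_shifts": [
            {"sample_id": s, "locus_id": l, "shift": v}
            for (s, l), v in sorted(truth.somatic_shifts.items())
        ],
        "germline_overrides": [
            {"patient_id": p, "locus_id": l, "tract_len_units": v}
            for (p, l), v in sorted(truth.germline_overrides.items())
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path: str | Path) -> CohortTruth:
    d = json.loads(Path(path).read_text())
    return CohortTruth(
        informative_locus_ids=set(d["informative_locus_ids"]),
        polymorphic_locus_ids=set(d["polymorphic_locus_ids"]),
        somatic_shifts={
            (e["sample_id"], e["locus_id"]): int(e["shift"]) for e in d["somatic_shifts"]
        },
        germline_overrides={
            (e["patient_id"], e["locus_id"]): int(e["tract_len_units"])
            for e in d["germline_overrides"]
        },
    )
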