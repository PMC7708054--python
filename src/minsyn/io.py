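"""File I/O: FASTA, GFF3, TSV manifests and the strength histogram.

Internal coordinates are 0-based half-open; GFF3 output is 1-based inclusive
per the standard.  Manifests open with ``#`` header lines carrying a
reproducibility block (config hash, seed, pool version).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import GeneratorConfig, MinSynLibrary
from .motifs import MotifHit

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_hits_gff3",
    "write_hits_tsv",
    "write_library_fasta",
    "write_features_gff3",
    "read_features_gff3",
    "write_manifest_tsv",
    "read_manifest_tsv",
    "plot_strength_histogram",
]

MANIFEST_COLUMNS = [
    "design_id",
    "n_cre",
    "cre_ids",
    "spacer_lengths",
    "length",
    "raw_score",
    "predicted_strength",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a (possibly line-wrapped, multi-record) FASTA."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def _gff3_escape(value: str) -> str:
    return str(value).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_hits_gff3(hits, path, source: str = "minsyn") -> None:
    """Motif hits as GFF3 ``TF_binding_site`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(sorted(hits, key=lambda h: h.sort_key), 1):
            attrs = (
                f"ID=hit{i};motif_id={_gff3_escape(h.motif_id)};"
                f"p_value={h.p_value:.3g}"
            )
            fh.write(
                f"{h.sequence_id}\t{source}\tTF_binding_site\t{h.start + 1}\t{h.end}\t"
                f"{h.score:.3f}\t{h.strand}\t.\t{attrs}\n"
            )


def write_hits_tsv(hits, path) -> None:
    rows = [
        {
            "sequence_id": h.sequence_id,
            "motif_id": h.motif_id,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "score": h.score,
            "p_value": h.p_value,
        }
        for h in sorted(hits, key=lambda h: h.sort_key)
    ]
    pd.DataFrame(
        rows,
        columns=["sequence_id", "motif_id", "start", "end", "strand", "score", "p_value"],
    ).to_csv(path, sep="\t", index=False)


def write_library_fasta(library: MinSynLibrary, path) -> None:
    write_fasta([(d.design_id, d.sequence) for d in library.designs], path)


def write_features_gff3(library: MinSynLibrary, path, source: str = "minsyn") -> None:
    """Per-segment features of every design, 1-based inclusive, sorted."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for design in library.designs:
            for j, (seg, start, end) in enumerate(design.coordinates(), 1):
                attrs = [f"ID={design.design_id}.{j}", f"kind={seg.kind}"]
                if seg.cre_id:
                    attrs.append(f"cre_id={_gff3_escape(seg.cre_id)}")
                    attrs.append(f"cre_class={seg.cre_class}")
                fh.write(
                    f"{design.design_id}\t{source}\t{_SO_TYPES.get(seg.kind, 'region')}\t"
                    f"{start + 1}\t{end}\t.\t+\t.\t{';'.join(attrs)}\n"
                )


_SO_TYPES = {
    "prefix": "sequence_feature",
    "spacer": "spacer",
    "cre": "regulatory_region",
    "tata": "TATA_box",
    "core": "core_promoter_element",
}
_KIND_FROM_SO = {v: k for k, v in _SO_TYPES.items()}


def read_features_gff3(path) -> pd.DataFrame:
    """Read a feature GFF3 back into 0-based half-open coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _src, so_type, start, end, _score, _strand, _phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            rows.append(
                {
                    "design_id": seqid,
                    "kind": fields.get("kind", _KIND_FROM_SO.get(so_type, so_type)),
                    "start": int(start) - 1,
                    "end": int(end),
                    "cre_id": fields.get("cre_id", ""),
                    "cre_class": fields.get("cre_class", ""),
                }
            )
    return pd.DataFrame(rows, columns=["design_id", "kind", "start", "end", "cre_id", "cre_class"])


def config_hash(cfg: GeneratorConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _manifest_frame(library: MinSynLibrary, scores: pd.DataFrame | None) -> pd.DataFrame:
    rows = []
    for design in library.designs:
        cre_ids = [s.cre_id for s in design.segments if s.kind == "cre"]
        spacer_lengths = [len(s.text) for s in design.segments if s.kind == "spacer"]
        rows.append(
            {
                "design_id": design.design_id,
                "n_cre": design.n_cre,
                "cre_ids": ",".join(cre_ids),
                "spacer_lengths": ",".join(str(x) for x in spacer_lengths),
                "length": len(design.sequence),
            }
        )
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS[:5])
    if scores is not None:
        frame = frame.merge(
            scores.drop(columns=[c for c in ("n_cre", "length") if c in scores.columns]),
            on="design_id",
            how="left",
        )
    for col in MANIFEST_COLUMNS:
        if col not in frame.columns:
            frame[col] = ""
    return frame[MANIFEST_COLUMNS]


def write_manifest_tsv(
    library: MinSynLibrary, path, scores: pd.DataFrame | None = None
) -> None:
    """Library manifest TSV with a reproducibility header block."""
    frame = _manifest_frame(library, scores)
    with open(path, "w", newline="") as fh:
        fh.write(f"# minsyn manifest\tconfig_hash={config_hash(library.config)}\n")
        fh.write(f"# seed={library.config.rng_seed}\tpool_version={library.pool_version}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_manifest_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        body = "".join(line for line in fh if not line.startswith("#"))
    return pd.read_csv(_io.StringIO(body), sep="\t")


def plot_strength_histogram(values, path, title: str = "Predicted MinSyn strength") -> None:
    """Histogram of predicted strengths across a library (matplotlib, Agg)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(list(values), bins=40, color="#4878a8", edgecolor="white")
    ax.set_xlabel("predicted strength (normalized expression)")
    ax.set_ylabel("designs")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
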