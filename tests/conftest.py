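"""Shared fixtures: tiny hand-built BAM/BED inputs and simulated data."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam
import pytest

from compase.alignment_io import TagConfig


def make_bam(
    path: Path,
    references: dict[str, int],
    records: list[dict],
    as_tag: str = "AS",
    nm_tag: str = "nM",
) -> Path:
    """Write a coordinate-sorted, indexed BAM from record dicts.

    Each record dict needs ``name``, ``ref``, ``pos``; optional keys:
    ``score`` (AS), ``nm`` (NM), ``flag``, ``length`` (default 10),
    ``nh``, ``skip_tags`` (emit no AS/NM tags).
    """
    ref_names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": references[n]} for n in ref_names],
    }
    records = sorted(records, key=lambda r: (ref_names.index(r["ref"]), r["pos"]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec["name"]
            seg.flag = rec.get("flag", 0)
            seg.reference_id = ref_names.index(rec["ref"])
            seg.reference_start = rec["pos"]
            seg.mapping_quality = rec.get("mapq", 60)
            length = rec.get("length", 10)
            seg.cigartuples = [(0, length)]
            seg.query_sequence = "A" * length
            tags = []
            if not rec.get("skip_tags"):
                tags.append((as_tag, rec.get("score", length), "i"))
                tags.append((nm_tag, rec.get("nm", 0), "i"))
            if "nh" in rec:
                tags.append(("NH", rec["nh"], "i"))
            seg.set_tags(tags)
            out.write(seg)
    pysam.index(str(path))
    return path


def write_bed(path: Path, rows: list[tuple[str, int, int, str]]) -> Path:
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    return path


@pytest.fixture
def tag_config() -> TagConfig:
    return TagConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250927)
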