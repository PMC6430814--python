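"""Shared fixtures: synthetic genomes and alignment files built at test time."""

from __future__ import annotations

import random
from pathlib import Path

import numpy as np
import pysam
import pytest


def write_fasta(path: Path, sequences: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return path


def make_bam(
    path: Path,
    reads: list[dict],
    references: dict[str, int],
) -> Path:
    """Write an indexed BAM from read dicts.

    Each read dict: chrom, pos (0-based), seq; optional qual (int or list),
    reverse (bool), read2 (default True), mapq (default 30), qname.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in references.items()],
    }
    ref_ids = {n: i for i, n in enumerate(references)}
    segs = []
    for i, rd in enumerate(reads):
        a = pysam.AlignedSegment()
        a.query_name = rd.get("qname", f"read{i}")
        a.query_sequence = rd["seq"]
        qual = rd.get("qual", 30)
        if isinstance(qual, int):
            qual = [qual] * len(rd["seq"])
        a.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in qual))
        a.reference_id = ref_ids[rd["chrom"]]
        a.reference_start = rd["pos"]
        a.mapping_quality = rd.get("mapq", 30)
        a.cigarstring = f"{len(rd['seq'])}M"
        flag = 0x1  # paired
        if rd.get("read2", True):
            flag |= 0x80
        else:
            flag |= 0x40
        if rd.get("reverse", False):
            flag |= 0x10
        a.flag = flag | rd.get("extra_flags", 0)
        segs.append(a)
    segs.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for a in segs:
            bam.write(a)
    pysam.index(str(path))
    return path


def random_sequence(length: int, seed: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def toy_genome(tmp_path):
    """A small FASTA with known motifs for filter tests.

    chrTest layout (0-based): positions 100-104 are AAAAA (homopolymer
    pentamer); elsewhere a fixed pseudo-random sequence with runs < 5.
    """
    seq = list(random_sequence(600, seed=7))
    seq[100:105] = list("AAAAA")
    # make sure nothing else reaches a 5-run: break runs deterministically
    s = "".join(seq)
    out = []
    run = 1
    for i, ch in enumerate(s):
        if 100 <= i < 105:
            out.append(ch)
            run = 1
            continue
        if out and ch == out[-1]:
            run += 1
            if run >= 4:
                ch = "ACGT"[("ACGT".index(ch) + 1) % 4]
                run = 1
        else:
            run = 1
        out.append(ch)
    path = write_fasta(tmp_path / "toy.fa", {"chrTest": "".join(out)})
    import pyfaidx

    return pyfaidx.Fasta(str(path))
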