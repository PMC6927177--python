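"""Shared fixtures: tiny annotations, alignments and simulated datasets.

All fixtures are generated programmatically; nothing is read from disk
except files the fixtures themselves write into tmp directories.
"""

from __future__ import annotations

import numpy as np
import pytest

GTF_LINES = [
    # two-exon gene on +, exons [100,200)+[300,400) -> tx length 200
    'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
    'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
    # single-exon gene on -, [1000,1130) -> tx length 130
    'chr1\tsrc\texon\t1001\t1130\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
]


@pytest.fixture(scope="session")
def gtf_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("anno") / "genes.gtf"
    path.write_text("\n".join(GTF_LINES) + "\n")
    return str(path)


@pytest.fixture(scope="session")
def models(gtf_file):
    from radar.genemodel import build_gene_models

    return build_gene_models(gtf_file, bin_size=50)


def sam_text(reads: list[tuple[str, int, int, bool]]) -> str:
    """Minimal single-end SAM: (chrom, pos0, length, reverse) per read."""
    header = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"
    lines = []
    for k, (chrom, pos, ln, rev) in enumerate(sorted(reads, key=lambda r: r[1])):
        flag = 16 if rev else 0
        lines.append(
            f"r{k}\t{flag}\t{chrom}\t{pos + 1}\t60\t{ln}M\t*\t0\t0\t"
            f"{'A' * ln}\t{'I' * ln}"
        )
    return header + "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def write_sam(tmp_path_factory):
    def _write(name: str, reads):
        path = tmp_path_factory.mktemp("sam") / f"{name}.sam"
        path.write_text(sam_text(reads))
        return str(path)

    return _write


@pytest.fixture(scope="session")
def null_dataset():
    """Small pure-null dataset from the random-effect generator."""
    from radar.simulate import simulate_radar_model

    return simulate_radar_model(n_bins=2000, n_samples=8, beta0=0.0, seed=11)


@pytest.fixture(scope="session")
def signal_dataset():
    from radar.simulate import simulate_radar_model

    return simulate_radar_model(n_bins=2000, n_samples=8, beta0=1.0, seed=12)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: deterministic and order-independent
    return np.random.default_rng(2024)
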