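import numpy as np
import pytest

from panelsplice.annotation import (
    GenePanel,
    TranscriptModel,
    index_from_transcripts,
)
from panelsplice.junctions import JunctionRecord


def make_index(transcripts_by_gene, classes=("PID",)):
    """AnnotationIndex over hand-written transcript models."""
    panel = GenePanel.from_entries([(g, list(classes)) for g in transcripts_by_gene])
    return index_from_transcripts(panel, transcripts_by_gene)


@pytest.fixture
def six_exon_gene_index():
    """One '+'-strand gene with six 100 bp exons separated by 400 bp introns.

    Exon i occupies [1 + 500*i, 100 + 500*i]; intron i is the 400 bp gap after
    exon i (0-based).
    """
    exons = [(1 + 500 * i, 100 + 500 * i) for i in range(6)]
    t = TranscriptModel("GENE1-T1", "GENE1", "chr1", "+", exons, coding_end_exon_index=5)
    return make_index({"GENE1": [t]})


def junction_record(chrom, start, end, strand_code=1, unique=50, annotated=1, mm=0):
    return JunctionRecord(chrom, start, end, strand_code, 1, annotated, unique, mm, 40)


def records_from_counts(index, counts_by_sample):
    """Turn {sample: {(chrom,start,end,strand): count}} into JunctionRecord lists."""
    strand_code = {"+": 1, "-": 2, ".": 0}
    out = {}
    for sample, counts in counts_by_sample.items():
        out[sample] = [
            junction_record(
                k[0], k[1], k[2], strand_code[k[3]], unique=c,
                annotated=1 if index.catalog.lookup(*k) else 0,
            )
            for k, c in sorted(counts.items())
        ]
    return out


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One demonstration cohort written to disk and analyzed end-to-end;
    shared across tests that only read its outputs."""
    from panelsplice.report import run_pipeline
    from panelsplice.simulate import demo_cohort

    base = tmp_path_factory.mktemp("demo")
    cohort = demo_cohort(seed=7)
    manifest = cohort.write(base / "cohort")
    findings = run_pipeline(manifest, base / "out", log=lambda *a: None)
    return {
        "cohort": cohort,
        "manifest": manifest,
        "out_dir": base / "out",
        "findings": findings,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
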