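import numpy as np
import pytest

from asquant.gene_models import GenomicInterval, Transcript, make_event
from asquant.quantify import CoverageTrack
from asquant.simulate import SimConfig, simulate_dataset


def make_transcript(exons, tid="t1", gene="g1", strand="+", cds=None, chrom="chr1"):
    return Transcript(
        id=tid,
        gene_id=gene,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds_start=cds[0] if cds else None,
        cds_end=cds[1] if cds else None,
    )


def make_se_event(affected, flank_up, flank_down, strand="+", gene="g1",
                  inc="t1", exc="t2", chrom="chr1"):
    return make_event(
        "SE",
        gene,
        [GenomicInterval(chrom, *affected, strand)],
        GenomicInterval(chrom, *flank_up, strand),
        GenomicInterval(chrom, *flank_down, strand),
        inc,
        exc,
    )


def uniform_track(chrom_len, segments, chrom="chr1", label=""):
    """Track with given (start, end, depth) segments, zero elsewhere."""
    arr = np.zeros(chrom_len, dtype=np.int64)
    for s, e, d in segments:
        arr[s:e] = d
    return CoverageTrack(depths={chrom: arr}, library_label=label)


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A small mixed-type simulated dataset shared across tests."""
    outdir = tmp_path_factory.mktemp("sim_small")
    config = SimConfig(seed=11, n_se=3, n_mxe=3, n_a5ss=3, n_a3ss=3)
    return simulate_dataset(config, str(outdir))


@pytest.fixture(scope="session")
def sim_utr(tmp_path_factory):
    """Cassette-only dataset with every event in the 5'-UTR."""
    outdir = tmp_path_factory.mktemp("sim_utr")
    config = SimConfig(seed=23, n_se=12, n_mxe=0, n_a5ss=0, n_a3ss=0,
                       fixed_region="5UTR")
    return simulate_dataset(config, str(outdir))
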