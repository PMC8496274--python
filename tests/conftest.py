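import numpy as np
import pytest

from methpore.formats import SiteMethylation


@pytest.fixture
def rng():
    return np.random.default_rng(20210526)


def make_site(
    contig="tig1",
    start=100,
    end=None,
    n_motifs=1,
    called_reads=10,
    meth_reads=6,
    group_seq=None,
):
    """Build a consistent SiteMethylation record from read counts."""
    if end is None:
        end = start
    if group_seq is None:
        group_seq = "AATTA" + "CGTTA" * n_motifs
    return SiteMethylation(
        contig=contig,
        start=start,
        end=end,
        n_motifs=n_motifs,
        called_sites=called_reads * n_motifs,
        called_methylated=meth_reads * n_motifs,
        frequency=meth_reads / called_reads,
        group_seq=group_seq,
    )


def write_call_tsv(path, rows, motif_col="num_motifs"):
    """Write a minimal per-read call table; rows are dicts."""
    cols = [
        "chromosome", "strand", "start", "end", "read_name",
        "log_lik_ratio", motif_col, "sequence",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            vals = [str(row.get(c if c != motif_col else "num_motifs", "")) for c in cols]
            fh.write("\t".join(vals) + "\n")


def call_row(contig="tig1", strand="+", start=100, end=100, read="r1",
             llr=5.0, n_motifs=1, seq="AATTACGTTAA"):
    return {
        "chromosome": contig, "strand": strand, "start": start, "end": end,
        "read_name": read, "log_lik_ratio": llr, "num_motifs": n_motifs,
        "sequence": seq,
    }
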