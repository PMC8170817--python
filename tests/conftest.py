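import pytest

from insec.correct import AlignmentArray
from insec.extract import ExtendedReference, MappedRead
from insec.io import Read
from insec.simulate import SimConfig, run_simulation


def make_ext(seq: str, gene_id: str = "g", left: int = 0, right: int = 0) -> ExtendedReference:
    core = seq[left:len(seq) - right if right else len(seq)]
    return ExtendedReference(gene_id=gene_id, core_seq=core,
                             left_flank=left, right_flank=right, ext_seq=seq)


def mapped(offset: int, seq: str, rid: str = "r", mism: int = 0) -> MappedRead:
    n = len(seq)
    return MappedRead(read=Read(rid, seq), offset=offset, cells=seq,
                      mismatches=mism, identity_pct=100.0 * (n - mism) / n)


def make_array(rows, ext_seq: str, left: int = 0, right: int = 0) -> AlignmentArray:
    """rows: list of (offset, cells, read_id)."""
    ext = make_ext(ext_seq, left=left, right=right)
    subset = [mapped(off, cells, rid) for off, cells, rid in rows]
    return AlignmentArray.build(subset, ext)


@pytest.fixture(scope="session")
def small_sim():
    """A 60 kb two-gene study at 30x, 1% errors, 0.1% SNP divergence."""
    cfg = SimConfig(genome_len=60_000,
                    gene_intervals=((10_000, 15_000), (30_000, 38_000)),
                    seed=7)
    return run_simulation(cfg)
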