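import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

_RC = str.maketrans("ACGTN", "TGCAN")


def brute_force_scan(genome, motifs):
    """Independent scanner oracle: enumerate every motif expansion and test
    each window of the doubled sequence by set membership (both strands).

    Returns {(position, strand): set of motifs} like scan_motifs, but built
    without regular expressions or wrap arithmetic beyond doubling.
    """
    from dnaakit.boxdensity import expand_motif

    L = len(genome.sequence)
    out = {}
    for motif in motifs:
        m = len(motif)
        fwd = expand_motif(motif)
        rev = {s.translate(_RC)[::-1] for s in fwd}
        doubled = genome.sequence + genome.sequence[: m - 1]
        for p in range(L):
            win = doubled[p:p + m]
            if win in fwd:
                out.setdefault((p, "+"), set()).add(motif)
            if win in rev:
                out.setdefault((p, "-"), set()).add(motif)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_genome(rng, length, gc=0.5, ori=0, ter=None):
    from dnaakit.boxdensity import CircularGenome

    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))
    return CircularGenome(id=f"rand{length}", sequence=seq, ori_position=ori,
                          ter_position=ter)
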