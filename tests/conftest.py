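import numpy as np
import pytest

from nucorg.genome import Feature, FeatureSet, GenomeLayout, GenomicInterval
from nucorg.tracks import ProbeTrack


@pytest.fixture
def toy_layout():
    return GenomeLayout((("chr1", 10_000), ("chr2", 8_000)))


def make_track(layout, records):
    """records: list of (chrom_name, start, end, value[, unique])."""
    names = layout.names
    chrom = np.array([names.index(r[0]) for r in records], dtype=np.int32)
    start = np.array([r[1] for r in records], dtype=np.int64)
    end = np.array([r[2] for r in records], dtype=np.int64)
    value = np.array([r[3] for r in records], dtype=float)
    unique = np.array([r[4] if len(r) > 4 else True for r in records], dtype=bool)
    return ProbeTrack(layout, chrom, start, end, value, unique)


def make_features(layout, records):
    """records: list of (chrom, start, end, feature_class) or with id."""
    feats = []
    for i, r in enumerate(records):
        fid = r[4] if len(r) > 4 else f"f{i}"
        feats.append(Feature(GenomicInterval(r[0], r[1], r[2]), r[3], fid))
    return FeatureSet(feats, layout)


def brute_force_overlap(fs, track, classes):
    """O(N*M) all-pairs interval intersection oracle."""
    names = track.layout.names
    mask = np.zeros(track.n_probes, dtype=bool)
    for i in range(track.n_probes):
        pc, ps, pe = names[track.chrom[i]], track.start[i], track.end[i]
        for f in fs.features:
            if f.feature_class not in classes:
                continue
            iv = f.interval
            if iv.chrom == pc and ps < iv.end and iv.start < pe:
                mask[i] = True
                break
    return mask


def random_overlap_instance(rng, max_probes=200, max_features=50):
    """A random toy genome with probes and two feature classes."""
    layout = GenomeLayout((
        ("chr1", int(rng.integers(2_000, 10_000))),
        ("chr2", int(rng.integers(2_000, 10_000))),
    ))
    n_probes = int(rng.integers(5, max_probes + 1))
    recs = []
    for _ in range(n_probes):
        chrom, length = layout.chromosomes[int(rng.integers(0, 2))]
        start = int(rng.integers(0, length - 60))
        recs.append((chrom, start, start + int(rng.integers(1, 60)),
                     float(rng.normal())))
    track = make_track(layout, recs)
    n_feat = int(rng.integers(1, max_features + 1))
    frecs = []
    for j in range(n_feat):
        chrom, length = layout.chromosomes[int(rng.integers(0, 2))]
        start = int(rng.integers(0, length - 400))
        cls = "tRNA" if rng.random() < 0.5 else "LTR"
        frecs.append((chrom, start, start + int(rng.integers(1, 400)), cls,
                      f"f{j}"))
    fs = make_features(layout, frecs)
    return layout, track, fs
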