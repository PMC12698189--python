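import pandas as pd
import pytest

import foottrack as ft
from foottrack.tracks import SignalTrack, TRACK_COLUMNS


def dataset_to_files(dataset, tmp_path, strand_tag=None):
    fasta = str(tmp_path / "ref.fa")
    sam = str(tmp_path / "reads.sam")
    dataset.write_fasta(fasta)
    dataset.write_sam(sam, strand_tag=strand_tag)
    return sam, fasta


def extract_from_dataset(dataset, tmp_path, **kwargs):
    sam, fasta = dataset_to_files(dataset, tmp_path)
    kwargs.setdefault("min_baseq", 0)
    kwargs.setdefault("min_mapq", 0)
    return ft.extract_conversion_track(sam, fasta, **kwargs)


def make_signal(chrom_pos_rate, n_total=100):
    """SignalTrack from [(chrom, pos, rate), ...] for constructed-signal tests."""
    rows = [(c, p, "+", r, n_total) for c, p, r in chrom_pos_rate]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "rate", "n_total"])
    return SignalTrack(df.sort_values(["chrom", "pos"]).reset_index(drop=True))


def uniform_signal(chrom, start, end, rate, every=2, n_total=100):
    return make_signal([(chrom, p, rate) for p in range(start, end, every)],
                       n_total=n_total)


def make_track(records, sample_id="t", min_total=1):
    """ConversionTrack from [(chrom, pos, strand, n_conv, n_total, context), ...]."""
    data = pd.DataFrame(records, columns=TRACK_COLUMNS)
    track = ft.ConversionTrack(data, sample_id=sample_id)
    track.global_rate = track.compute_global_rate(min_total=min_total)
    return track


@pytest.fixture(scope="session")
def occupancy_dataset():
    """One bound TF site (theta=0.7) inside an open region, deep coverage."""
    cfg = ft.SimulationConfig(
        seed=11, contigs={"chrSim": 6000}, ocrs=[("chrSim", 1000, 5000)],
        tf_sites=[ft.TFSite("TF1", "TGACGTCACGCG", 2500, 0.7)],
        n_molecules=2000, restrict_to=[("chrSim", 1500, 3500)],
        fragment_len_mean=250, fragment_len_sd=40)
    ref = ft.simulate_reference(cfg)
    return ft.simulate_molecules(ref, cfg)


@pytest.fixture(scope="session")
def naked_dataset():
    """Protein-free DNA, uniform conversion probability 0.8."""
    cfg = ft.SimulationConfig(
        seed=7, contigs={"chrNak": 30_000}, naked=True, naked_rate=0.8,
        n_molecules=4000, fragment_len_mean=200, fragment_len_sd=30)
    ref = ft.simulate_reference(cfg)
    return ft.simulate_molecules(ref, cfg)


@pytest.fixture(scope="session")
def occupancy_track(occupancy_dataset, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("occ")
    return extract_from_dataset(occupancy_dataset, tmp)


@pytest.fixture(scope="session")
def naked_track(naked_dataset, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("naked")
    return extract_from_dataset(naked_dataset, tmp)
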