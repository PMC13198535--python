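import numpy as np
import pytest

from spindlekit.io import Event, EventList, Hypnogram
from spindlekit.preprocessing import extract_n2_blocks
from spindlekit.synth import SpindleGenParams, gen_recording
from spindlekit.unet import TrainConfig, UNetConfig, build_unet, train


def all_n2_blocks(n_blocks: int, seed: int, density_spm: float = 6.0,
                  block_epochs: int = 1):
    """High-SNR single-N2-epoch training blocks with block-local labels."""
    seeds = np.random.SeedSequence(seed).generate_state(n_blocks) % (2 ** 31)
    params = SpindleGenParams(density_spm=density_spm)
    blocks, labels = [], []
    for i in range(n_blocks):
        hyp = Hypnogram(["N2"] * block_epochs)
        rec, truth = gen_recording(hyp, channels=["C3"],
                                   spindle_params=params, seed=int(seeds[i]))
        sig, fs = rec.channel("C3")
        blk = extract_n2_blocks(sig, fs, hyp, channel="C3")[0]
        blocks.append(blk.samples)
        labels.append(EventList([
            Event(e.onset_s - blk.start_s, e.duration_s) for e in truth
        ]))
    return blocks, labels


@pytest.fixture(scope="session")
def small_trained_model():
    """A quickly trained small segmenter shared by pipeline/CLI smoke tests."""
    blocks, labels = all_n2_blocks(16, seed=11)
    model = build_unet(UNetConfig(base_filters=4), seed=3)
    cfg = TrainConfig(max_epochs=25, patience=25, seed=3)
    model, history = train(model, blocks, labels, cfg)
    return model, history
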