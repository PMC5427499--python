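import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cndiverse import GenomeModel, Chromosome, WindowTrack, build_genome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    return build_genome(2, 300_000, 0.45, seed=11, essential_gene_spacing=45_000)


@pytest.fixture(scope="session")
def one_chrom_genome() -> GenomeModel:
    return GenomeModel([Chromosome("chr1", 200_000, 90_000, 90_500)])


def make_track(
    genome: GenomeModel,
    window: int = 250,
    states: dict[str, np.ndarray] | None = None,
    strain_id: str = "s1",
) -> WindowTrack:
    """Build a normalized-looking track directly from CN states.

    ratio is set equal to the state (plus nothing), so segment()/genic_cn()
    can be unit-tested without running the normalizer.
    """
    frames = []
    for c in genome.chromosomes:
        starts = genome.window_starts(c.name, window)
        st = np.ones(len(starts), dtype=np.int64)
        if states and c.name in states:
            arr = np.asarray(states[c.name], dtype=np.int64)
            st[: len(arr)] = arr
        frames.append(
            pd.DataFrame(
                {
                    "chrom": c.name,
                    "start": starts,
                    "depth": 30 * st,
                    "gc": 0.45,
                    "ratio": st.astype(float),
                    "cn_state": st,
                }
            )
        )
    return WindowTrack(strain_id, window, pd.concat(frames, ignore_index=True))


def uniform_depth_frame(genome: GenomeModel, window: int = 250, depth: int = 30) -> pd.DataFrame:
    frames = []
    for c in genome.chromosomes:
        starts = genome.window_starts(c.name, window)
        frames.append(
            pd.DataFrame(
                {"chrom": c.name, "start": starts, "depth": depth, "gc": 0.45}
            )
        )
    return pd.concat(frames, ignore_index=True)
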