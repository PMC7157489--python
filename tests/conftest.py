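import numpy as np
import pandas as pd
import pytest

from artstat.plsr import GENRES
from artstat.stats import STAT_COLUMNS
from artstat.synthetic import gen_genre_dataset, gen_rating_dataset, noise_sd_for_r2


@pytest.fixture(scope="session")
def rating_dataset():
    """n=200 dataset with actives SL_L, FD_L, EN_L at generative R^2 = 0.5."""
    w = np.zeros(9)
    w[[0, 3, 6]] = 0.5
    sd = noise_sd_for_r2(w, 0.5)
    df, truth = gen_rating_dataset(200, w, sd, seed=11)
    return df, truth


@pytest.fixture(scope="session")
def null_genre_dataset():
    """Eight genres, 50 records each, no genre effect, no active predictors."""
    specs = {g: {"n": 50, "weights": np.zeros(9), "noise_sd": 1.0}
             for g in GENRES}
    df, truth = gen_genre_dataset(specs, seed=5)
    return df, truth


def records_from_arrays(X, y, genre="all"):
    df = pd.DataFrame(np.asarray(X, float), columns=list(STAT_COLUMNS))
    df.insert(0, "image_id", [f"im{i}" for i in range(len(df))])
    df.insert(1, "genre", genre)
    df.insert(2, "rating", np.asarray(y, float))
    return df
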