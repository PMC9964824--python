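import pandas as pd
import pytest

from hazecoast import pipeline as pl
from hazecoast import synthetic as syn


def make_series(values: dict, start="2020-01-01", meta=None):
    """Build an HourlyStationSeries from equal-length per-variable lists."""
    import numpy as np

    from hazecoast.station_io import (MISSING, VALID, HourlyStationSeries,
                                      StationMeta)
    n = len(next(iter(values.values())))
    idx = pd.date_range(start, periods=n, freq="h")
    data = pd.DataFrame(values, index=idx, dtype=float)
    flags = pd.DataFrame(np.where(data.notna(), VALID, MISSING),
                         index=idx, columns=data.columns)
    meta = meta or StationMeta("T01", 13.67, 100.61)
    return HourlyStationSeries(meta, data, flags)


@pytest.fixture(scope="session")
def noiseless_scenario(tmp_path_factory):
    """Default winter scenario with all noise off, written to disk."""
    cfg = syn.default_scenario_config(seed=11)
    cfg.noise_sd = {k: 0.0 for k in cfg.noise_sd}
    scn = syn.generate_scenario(cfg)
    outdir = tmp_path_factory.mktemp("scn0")
    syn.write_scenario(scn, outdir)
    return scn, outdir


@pytest.fixture(scope="session")
def noiseless_result(noiseless_scenario):
    scn, outdir = noiseless_scenario
    cfg = pl.config_for_scenario_dir(outdir)
    return pl.run_pipeline(cfg, write=False)


@pytest.fixture(scope="session")
def noisy_scenario(tmp_path_factory):
    """Default winter scenario with default noise, written to disk."""
    scn = syn.generate_scenario(syn.default_scenario_config(seed=5))
    outdir = tmp_path_factory.mktemp("scn1")
    syn.write_scenario(scn, outdir)
    return scn, outdir


@pytest.fixture(scope="session")
def noisy_result(noisy_scenario):
    scn, outdir = noisy_scenario
    cfg = pl.config_for_scenario_dir(outdir)
    return pl.run_pipeline(cfg, write=False)
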