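import numpy as np
import pandas as pd
import pytest

from leafgas import GasExchangeTimeseries, SimulationSpec, simulate_run

NO_NOISE = {"gsw": 0.0, "A": 0.0}


def make_irga_text(
    path,
    columns,
    rows,
    units=None,
    group_row=True,
    extra_lines=(),
):
    """Write a minimal LI-6800-style TSV: optional group row, variable names,
    optional units row, then data rows (strings passed through verbatim)."""
    lines = []
    if group_row:
        lines.append("\t".join(["GasEx"] * len(columns)))
    lines.append("\t".join(columns))
    if units is not None:
        lines.append("\t".join(units))
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    for extra in extra_lines:
        lines.append(extra)
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def minimal_irga_file(tmp_path):
    return make_irga_text(
        tmp_path / "run.txt",
        ["elapsed", "Qin", "gsw", "A"],
        [[0, 1000, 0.25, 18.0], [60, 1000, 0.26, 18.2], [120, 1000, 0.27, 18.4]],
        units=["s", "umol m-2 s-1", "mol m-2 s-1", "umol m-2 s-1"],
    )


@pytest.fixture(scope="session")
def noisefree_run():
    """(timeseries, truth) for the standard four-phase protocol, zero noise."""
    spec = SimulationSpec(noise_sd=dict(NO_NOISE), seed=11)
    return simulate_run(spec)


@pytest.fixture
def constant_ts():
    t = np.arange(0.0, 1200.0, 60.0)
    df = pd.DataFrame(
        {"t": t, "q_in": np.full_like(t, 500.0), "gsw": np.full_like(t, 0.25),
         "A": np.full_like(t, 17.5)}
    )
    return GasExchangeTimeseries(df, {})
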