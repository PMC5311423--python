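import numpy as np
import pytest

from pedinfuse.formulary import Patient, default_formulary


@pytest.fixture(scope="session")
def formulary():
    return default_formulary()


@pytest.fixture(scope="session")
def infant():
    """The 7-kg scenario patient."""
    return Patient(weight=7.0)


# Published summary table of the trial: (outcome, period, method) ->
# (mean s, sd s, printed 95% CI bounds), n=10 everywhere.
TABLE2 = {
    ("tdp", 1, "app"): (128.1, 36.5, 102.0, 154.2),
    ("tdp", 1, "conventional"): (308.1, 128.3, 216.3, 399.9),
    ("tdp", 2, "app"): (143.7, 21.9, 128.1, 159.3),
    ("tdp", 2, "conventional"): (198.4, 60.2, 155.3, 241.5),
    ("tdd", 1, "app"): (213.5, 59.9, 170.6, 256.4),
    ("tdd", 1, "conventional"): (390.8, 129.3, 298.3, 483.3),
    ("tdd", 2, "app"): (221.8, 33.0, 198.2, 245.4),
    ("tdd", 2, "conventional"): (276.7, 70.6, 226.2, 327.2),
}


def exact_moment_sample(mean: float, sd: float, n: int = 10) -> np.ndarray:
    """n values whose sample mean and sample sd (ddof=1) match exactly."""
    v = np.arange(n, dtype=float) - (n - 1) / 2
    z = v / v.std(ddof=1)
    return mean + sd * z


@pytest.fixture(scope="session")
def table2_records():
    """Per-nurse records whose cell summaries equal the published table.

    TDP and TDD samples are moment-matched per cell and paired rank-for-rank,
    which keeps tdd >= tdp everywhere.  Error flags: 8/10 conventional in
    period 1, 6/10 in period 2, none with the app.
    """
    from pedinfuse.trial_sim import NurseRecord

    records = []
    for period, drug, rate in [(1, "dopamine", 5.0), (2, "norepinephrine", 0.1)]:
        for method in ("app", "conventional"):
            arm = ("A" if method == "app" else "B") if period == 1 else (
                "B" if method == "app" else "A"
            )
            offset = 0 if arm == "A" else 10
            tdp_m, tdp_s, *_ = TABLE2[("tdp", period, method)]
            tdd_m, tdd_s, *_ = TABLE2[("tdd", period, method)]
            tdp = exact_moment_sample(tdp_m, tdp_s)
            tdd = exact_moment_sample(tdd_m, tdd_s)
            n_err = {"app": 0, "conventional": 8 if period == 1 else 6}[method]
            for i in range(10):
                err = i < n_err
                records.append(
                    NurseRecord(
                        nurse_id=f"N{offset + i + 1:02d}",
                        arm=arm,
                        period=period,
                        method=method,
                        drug=drug,
                        tdp_s=float(tdp[i]),
                        tdd_s=float(tdd[i]),
                        prescribed_ug_kg_min=rate,
                        delivered_ug_kg_min=rate * (10.0 if err else 1.0),
                        error_flag=err,
                    )
                )
    return records
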