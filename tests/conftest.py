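import numpy as np
import pytest

import fallsim as fs


@pytest.fixture()
def params():
    """Fresh default parameter set (tests may mutate freely)."""
    return fs.build_default_parameters()


@pytest.fixture(scope="session")
def small_summaries():
    """All eight strategies at a small scale, for the analysis layers."""
    p = fs.build_default_parameters()
    spec = fs.PopulationSpec(n_baseline=600)
    return {name: fs.run_strategy(p, fs.make_strategy(name, p), spec,
                                  master_seed=11, horizon=15)
            for name in fs.STRATEGY_NAMES}


def brute_force_frontier(points):
    """Independent dominance oracle: pairwise strong dominance, then
    extended dominance via explicit two-point convex combinations.

    Returns {strategy: classification} with the same labels as
    :func:`fallsim.dominance_frontier`.  Assumes generic (tie-free) inputs.
    """
    from fallsim.cea import DOMINATED, EXT_DOMINATED, ON_FRONTIER

    pts = {p.strategy: (p.public_cost, p.societal_qalys) for p in points}
    out = {}
    for name, (c, q) in pts.items():
        if any(o != name and c2 <= c and q2 >= q and (c2 < c or q2 > q)
               for o, (c2, q2) in pts.items()):
            out[name] = DOMINATED
    alive = {n: v for n, v in pts.items() if n not in out}
    for name, (c, q) in alive.items():
        dominated = False
        for a, (ca, qa) in alive.items():
            for b, (cb, qb) in alive.items():
                if a == b or name in (a, b) or not ca < c < cb:
                    continue
                t = (cb - c) / (cb - ca)
                if t * qa + (1 - t) * qb > q:
                    dominated = True
        if dominated:
            out[name] = EXT_DOMINATED
    for name in pts:
        out.setdefault(name, ON_FRONTIER)
    return out


def random_points(rng, n):
    """Generic random strategy points (distinct costs and QALYs)."""
    costs = rng.uniform(0, 1e6, n)
    qalys = rng.uniform(0, 5e3, n)
    return [fs.StrategyPoint(strategy=f"S{i}", public_cost=float(costs[i]),
                             health_qalys=float(qalys[i]))
            for i in range(n)]


@pytest.fixture(scope="session")
def table1_points():
    """The bundled incremental (public cost, societal QALY) pairs."""
    import importlib.resources

    import pandas as pd
    src = importlib.resources.files("fallsim") / "data" / "table1.csv"
    frame = pd.read_csv(src.open())
    return [fs.StrategyPoint(strategy=row["strategy"],
                             public_cost=float(row["incremental_public_cost"]),
                             health_qalys=float(row["incremental_societal_qalys"]))
            for _, row in frame.iterrows()]


@pytest.fixture()
def null_intervention_params(params):
    """Relative risk 1 and zero intervention costs for every pathway."""
    for pw in ("R", "P", "SR"):
        iv = params.intervention_params[pw]
        iv.relative_risk = 1.0
        iv.public_cost = 0.0
        iv.copayment = 0.0
        iv.participant_time_cost = 0.0
        iv.caregiver_time_cost = 0.0
    return params


def summaries_equal(a, b) -> bool:
    from fallsim.microsim import OUTCOME_FIELDS
    return (np.array_equal(a.persons, b.persons)
            and all(np.array_equal(getattr(a, f), getattr(b, f))
                    for f in OUTCOME_FIELDS))
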