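"""Independent stock-and-flow oracle for degenerate scenarios.

Evolves aggregate cohort groups (count, age, years-in-state, nationality,
retirement age) with deterministic annual flows — ageing, retirement,
certification, all-or-nothing foreign attrition, capacity-constrained
promotion by seniority, quota refill. Valid only when every stochastic element
of the microsimulation is degenerate (zero retirement-age SD, hazard 0 or 1,
single-nationality entrant pools), in which case the per-person engine must
reproduce these censuses exactly.
"""

from dataclasses import dataclass, replace

T, TR, FX = "TRAINING", "TRANSITION", "FIXED"


@dataclass
class Group:
    state: str
    count: int
    age: float
    yis: float
    foreign: bool = False
    ret: float = 62.0


def oracle_trajectory(
    groups,
    *,
    quota,
    capacity,
    n_years,
    training_years=5.0,
    return_policy=True,
    hazard=0.0,
    entrant_foreign=False,
    entrant_ret=62.0,
    entrant_age=28.0,
):
    assert hazard in (0.0, 1.0), "oracle only covers degenerate hazards"
    groups = [replace(g) for g in groups]
    records = []
    for _ in range(n_years):
        for g in groups:
            g.age += 1
            g.yis += 1

        n_ret = sum(g.count for g in groups if g.age >= g.ret)
        groups = [g for g in groups if g.age < g.ret]

        n_dep = 0
        kept = []
        for g in groups:
            if g.state == T and g.yis >= training_years:
                if return_policy and g.foreign:
                    n_dep += g.count
                    continue
                g.state = TR
                g.yis = 0.0
            kept.append(g)
        groups = kept

        if hazard == 1.0:
            n_dep += sum(g.count for g in groups if g.state == TR and g.foreign)
            groups = [g for g in groups if not (g.state == TR and g.foreign)]

        vac = capacity - sum(g.count for g in groups if g.state == FX)
        pool = sorted(
            (g for g in groups if g.state == TR), key=lambda g: (-g.yis, -g.age)
        )
        for g in pool:
            if vac <= 0:
                break
            take = min(vac, g.count)
            if take == g.count:
                g.state = FX
                g.yis = 0.0
            else:
                g.count -= take
                groups.append(Group(FX, take, g.age, 0.0, g.foreign, g.ret))
            vac -= take

        n_new = quota - sum(g.count for g in groups if g.state == T)
        if n_new > 0:
            groups.append(
                Group(T, n_new, entrant_age, 0.0, entrant_foreign, entrant_ret)
            )

        records.append({
            "n_training": sum(g.count for g in groups if g.state == T),
            "n_transition": sum(g.count for g in groups if g.state == TR),
            "n_fixed": sum(g.count for g in groups if g.state == FX),
            "n_retired": n_ret,
            "n_departed": n_dep,
        })
    return records
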