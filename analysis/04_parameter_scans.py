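#!/usr/bin/env python
"""Sensitivity of the steady invasion rate to the model's dials.

Measures the amplification rate at a fixed copy number while scanning
transposase expression, genome size, nuclear volume, end affinity (k1),
maturation rate (k3), an inhibitory secondary binding site, and the
dimerization-end-occlusion variants.  Writes results/parameter_scans.tsv.

Finding: under assembly-site occlusion the rate is inversely proportional
to expression and to end affinity, directly proportional to genome size,
insensitive to nuclear volume and to a 1000-fold drop in the maturation
rate; a secondary inhibitory site scales the rate with the reciprocal of
its affinity without changing the linear dynamics; the DEO steady rate is
independent of the end-association rate as long as dimerization is fixed.
"""

import os

import pandas as pd

from transposim.simulation import get_scenario, rate_at_copy_number, run_invasion, steady_state_rate

OUT = os.path.join(os.path.dirname(__file__), os.pardir, "results")
os.makedirs(OUT, exist_ok=True)

rows = []


def record(scan, condition, rate, reference):
    rows.append(dict(scan=scan, condition=condition, rate=rate,
                     relative=rate / reference))


# expression (crowded allosteric, at 1000 copies)
base = get_scenario("snec_invivo_allosteric").with_overrides(t_span=1e12)
r_ref = rate_at_copy_number(base, 1000.0)
for e in (100.0, 500.0, 1000.0, 2500.0):
    r = rate_at_copy_number(base.with_overrides(ctx={"expression_per_copy": e}), 1000.0)
    record("expression_per_copy", f"{e:g}", r, r_ref)

# genome size and nuclear volume
for g in (3e9, 6e9, 12e9):
    r = rate_at_copy_number(base.with_overrides(ctx={"genome_size": g}), 1000.0)
    record("genome_size", f"{g:g}", r, r_ref)
for v in (50.0, 500.0, 5000.0):
    r = rate_at_copy_number(base.with_overrides(ctx={"nuclear_volume": v}), 1000.0)
    record("nuclear_volume", f"{v:g}", r, r_ref)

# end affinity (dilute allosteric, per-landmark protocol)
aff = get_scenario("snec_invitro_allosteric").with_overrides(t_span=1e10)
r_aff = rate_at_copy_number(aff, 1000.0)
for f in (0.2, 1.0, 5.0):
    r = rate_at_copy_number(aff.with_overrides(params={"k1": 3.8e8 * f}), 1000.0)
    record("k1_factor", f"{f:g}", r, r_aff)

# maturation rate (established steady state)
est = get_scenario("snec_invivo_allosteric").with_overrides(
    t_span=2e9, n0=200.0, equilibrated_start=True, grid="linear"
)
r_k3 = steady_state_rate(run_invasion(est)).rate
for k3 in (1.4e-3, 1.4e-6):
    r = steady_state_rate(
        run_invasion(est.with_overrides(params={"k3": k3}))
    ).rate
    record("k3", f"{k3:g}", r, r_k3)

# secondary inhibitory site (crowded non-allosteric, at 5000 copies)
sec0 = get_scenario("snec_invivo").with_overrides(t_span=1e10)
r_sec = rate_at_copy_number(sec0, 5000.0)
record("secondary_site", "none", r_sec, r_sec)
for name, label in (("snec_invivo_secondary_1x", "1x"),
                    ("snec_invivo_secondary_2x", "2x")):
    r = rate_at_copy_number(get_scenario(name).with_overrides(t_span=1e10), 5000.0)
    record("secondary_site", label, r, r_sec)

# DEO: end-association invariance (dimerization fixed) and dimer affinity
deo = get_scenario("deo_invitro").with_overrides(params={"deo_dimerization_k": 3.8e8})
r_deo = rate_at_copy_number(deo, 2e5)
for f in (0.2, 1.0, 5.0):
    r = rate_at_copy_number(deo.with_overrides(params={"k1": 3.8e8 * f}), 2e5)
    record("deo_k1_factor", f"{f:g}", r, r_deo)
deo_v = get_scenario("deo_invivo").with_overrides(t_span=1e10)
r_dv = rate_at_copy_number(deo_v, 1e5)
record("deo_dimer_affinity", "1x", r_dv, r_dv)
r_d2 = rate_at_copy_number(
    deo_v.with_overrides(params={"deo_dimer_end_affinity_multiplier": 2.0}), 1e5
)
record("deo_dimer_affinity", "2x", r_d2, r_dv)

df = pd.DataFrame(rows)
df.to_csv(os.path.join(OUT, "parameter_scans.tsv"), sep="\t", index=False)
print(df.to_string(index=False))
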