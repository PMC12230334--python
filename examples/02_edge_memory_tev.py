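"""Edge memory and the total edge volume (TEV) time trend.

Simulates a study of 30 measurements whose forward/backward edge
displacement decays linearly to zero at t_zero = 18.8 h, computes the TEV
of every scan pair and fits the linear TEV(t_P) trend, recovering the
configured zero-crossing time.
"""

import sicmorph as sm
from sicmorph import morphodynamics as md

records, ledger = sm.simulate_study(n_records=30, master_seed=1, t_zero_h=18.8)

points = []
for rec, truth in zip(records, ledger["records"]):
    tev = sm.total_edge_volume(rec.pair)
    points.append(
        md.TevPoint(
            id=rec.id, tev=tev, t_prep=rec.t_prep,
            group=truth["group_true"], complete=rec.complete,
        )
    )

print("id      t_P[h]   TEV[nm^3]   group")
for p in points[:6]:
    print(f"{p.id}  {p.t_prep:6.2f}   {p.tev:.3e}  {p.group}")
print("...")

fit = md.tev_trend(points)  # partial + submitochondrial records excluded
print(f"\nslope      = {fit.slope:.3e} nm^3/h")
print(f"intercept  = {fit.intercept:.3e} nm^3")
print(f"t_zero     = {fit.t_zero:.1f} h   (configured decay time: 18.8 h)")
print(f"r^2        = {fit.r_squared:.2f}  over n = {fit.n_points} measurements")

# TEV integrates |backward - forward| height disagreement over the frame; on
# active mitochondria it is dominated by the lateral edge displacement and
# its extrapolated zero crossing estimates when morphodynamic activity ends.
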