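"""Reward omission: the trained network signals a negative prediction error.

After the standard protocol, the cue is presented alone.  The accumbens
interval code fires at the expected reward time, inhibits the ventral
pallidum, disinhibits the habenula/RMTg pathway, and the dopaminergic
rate drops to zero - the omission dip.
"""

from vtanet import build_network, has_sub_criterion_run, run_standard_protocol
from vtanet.protocol import TrialSpec, make_trial, run_trial

net = build_network(rng=1)
run_standard_protocol(net, record=())

tr = run_trial(net, make_trial(TrialSpec(1, "omission")), learning_on=False,
               record=("VTA", "NAcc", "VP", "LHb", "RMTg"))
t_exp = tr.events["expected_us"]        # 3000 ms for the 2-s association
post = tr["VTA"][t_exp:t_exp + 1000]

print(f"expected reward time: {t_exp} ms after trial start (never delivered)")
print(f"min VTA rate in the following second: {post.min():.3f}")
print(f"sustained (>=20 ms) silence below 0.05: "
      f"{has_sub_criterion_run(post, 0.05, 20)}")
print(f"max NAcc rate near the expected time: "
      f"{tr['NAcc'][t_exp - 100:t_exp + 100].max():.2f}")
print(f"VP rate at the expected time: {tr['VP'][t_exp + 60]:.2f} "
      f"(tonic baseline 0.5)")
print(f"peak LHb / RMTg rates after omission: "
      f"{tr['LHb'][t_exp:t_exp + 300].max():.2f} / "
      f"{tr['RMTg'][t_exp:t_exp + 300].max():.2f}")

# The dip (VTA at 0) together with accumbens firing at the expected time
# and transient habenular activation reproduces the negative
# reward-prediction-error signature.
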