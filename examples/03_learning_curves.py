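"""Learning curves: how beta and gamma shape anticipatory looking.

Simulates the eyebrow-raise condition at strong learning (beta = 5,
gamma = 2) and with learning absent (beta = 0), baseline-corrects the
anticipatory Eyes-Mouth scores per virtual participant, and prints the
start/end points of the regression line through each group-mean curve.
"""

from gazesim import Params, Protocol, simulate_experiment
from gazesim.analysis import experiment_endpoints
from gazesim.synth import protocol_streams

for beta, label in ((5.0, "strong learning"), (0.0, "no learning")):
    protocol = Protocol(conditions=("ER",), master_seed=11,
                        params=Params(beta=beta, gamma=2.0, theta=0.0))
    result = simulate_experiment(protocol, protocol_streams(protocol))
    ep = experiment_endpoints(result, baseline="participant")["ER"]
    print(f"beta={beta} ({label}): corrected curve start={ep.start:+.3f} "
          f"end={ep.end:+.3f} gain={ep.end - ep.start:+.3f}")

print("\nWith learning, the corrected anticipatory score climbs across the 19")
print("trials (positive gain): the model looks toward the eyes increasingly")
print("before the eyebrow raise. Without it the fitted line stays flat.")
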