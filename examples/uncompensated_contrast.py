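"""Why delay compensation matters: the same reflex with and without it.

Runs the identical plant, head motion and 10 ms sensory delay twice -- once
with the delay estimator and state predictor active, once feeding the raw
delayed error straight to the controller -- and compares the retinal slip.
"""

from delayloop import SimulationConfig, compute_metrics, run_closed_loop

compensated = run_closed_loop(SimulationConfig(scenario="compensated_constant_delay"))
uncompensated = run_closed_loop(SimulationConfig(scenario="uncompensated_delay"))

m_c = compute_metrics(compensated)
m_u = compute_metrics(uncompensated)

print(f"compensated rms slip   : {m_c['rms_slip']:10.3f} deg/s")
print(f"uncompensated rms slip : {m_u['rms_slip']:10.3f} deg/s")
print(f"degradation factor     : {m_u['rms_slip'] / m_c['rms_slip']:10.0f} x")
print()
print("Without compensation the high-gain reflex reacts to a 10 ms-old world:")
print("the loop develops fast oscillations of the eye around the head velocity")
print("(the saturation-bounded oscillation seen here), while the compensated")
print("loop tracks smoothly. Disabling only the estimator or only the")
print("predictor degrades the loop the same way.")
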