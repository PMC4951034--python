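"""Rigidly register a displaced motion frame back to the reference.

Perturbs a synthetic scapula by a known rigid motion plus surface noise,
recovers the alignment with ICP and reports the residual pose error -- the
accuracy with which humeral motion can be expressed in a fixed glenoid
frame.
"""

import numpy as np

from glenokin import RigidTransform, register_rigid
from glenokin.synthetic import _scapula_blade

scapula = np.asarray(_scapula_blade().vertices)
rng = np.random.default_rng(3)

true_motion = RigidTransform.from_axis_angle([0.2, 1.0, 0.4], 10.0, [3.0, -2.0, 5.0])
moving = true_motion.apply(scapula) + rng.normal(0, 0.2, scapula.shape)

report = register_rigid(moving, scapula)
residual = report.transform.compose(true_motion)

print(f"ICP iterations:        {report.iterations} (converged={report.converged})")
print(f"RMS before -> after:   {report.rms_before:.3f} -> {report.rms_after:.3f} mm")
print(f"rotation error:        {residual.rotation_angle_deg():.4f} deg")
print(f"translation error:     {np.linalg.norm(residual.translation):.4f} mm")
# With 0.2 mm vertex noise the 10 deg / ~6 mm perturbation is undone to a
# few hundredths of a degree / millimetre -- far below the kinematic
# signals of interest (millimetres of humeral-head translation).
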