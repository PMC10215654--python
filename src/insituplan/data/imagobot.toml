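# Default 5-DoF deposition-arm fixture (MOVEO-like proportions).
# All link dimensions and limits are editable conventions of this package,
# not measurements of any physical arm. Units: mm, degrees; z up.
#
# Layout: base yaw about z, three pitch joints about y, wrist roll about the
# tool z axis; the nozzle tip sits 90 mm below the wrist along the tool axis.

tool_offset = [0.0, 0.0, -90.0]

[[joint]]            # base yaw
axis = [0.0, 0.0, 1.0]
translation = [0.0, 0.0, 231.5]
limits_deg = [-180.0, 180.0]

[[joint]]            # shoulder pitch
axis = [0.0, 1.0, 0.0]
translation = [0.0, 0.0, 221.0]
limits_deg = [-95.0, 95.0]

[[joint]]            # elbow pitch
axis = [0.0, 1.0, 0.0]
translation = [0.0, 0.0, 221.0]
limits_deg = [-150.0, 150.0]

[[joint]]            # wrist pitch
axis = [0.0, 1.0, 0.0]
translation = [0.0, 0.0, 60.0]
limits_deg = [-165.0, 165.0]

[[joint]]            # wrist roll
axis = [0.0, 0.0, 1.0]
translation = [0.0, 0.0, 0.0]
limits_deg = [-180.0, 180.0]
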