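[experiment]
cycles = 2
flowcells = A
autofocus = partial_once

[reagents]
blocking = 1
imaging = 2
elution = 3
primary = 4, chilled
secondary = 5, chilled
primary_1 = 4, chilled
secondary_1 = 5, chilled
primary_2 = 6, chilled
secondary_2 = 7, chilled

[rois]
section_1 = 2.0, 5.0, 5.0, 10.0, 1

[imaging]
flow_rate = 500.0
z_planes = 1
laser_532 = 100.0
laser_660 = 100.0

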