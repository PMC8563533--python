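# ILLUSTRATIVE cutoff configuration -- NOT authoritative norms.
# Boundary values here exist only to demonstrate the file format and to
# let the banding/labelling machinery run end to end; real analyses must
# substitute published cutoff values for each informant version.
#
# direction: high_worse  -> score <= normal is 'normal', <= borderline is
#                           'borderline', above is 'abnormal'
# direction: low_worse   -> read from the top (strengths scales)
# 'total' refers to the summed four difficulties subscales (0-40).
parent:
  conduct:
    borderline: 5.0
    direction: high_worse
    normal: 3.0
  emotional:
    borderline: 5.0
    direction: high_worse
    normal: 3.0
  hyperactivity:
    borderline: 5.0
    direction: high_worse
    normal: 3.0
  prosocial:
    borderline: 5.0
    direction: low_worse
    normal: 6.0
  social:
    borderline: 5.0
    direction: high_worse
    normal: 3.0
  total:
    borderline: 19.0
    direction: high_worse
    normal: 15.0
self:
  conduct:
    borderline: 5.0
    direction: high_worse
    normal: 3.0
  emotional:
    borderline: 5.0
    direction: high_worse
    normal: 3.0
  hyperactivity:
    borderline: 5.0
    direction: high_worse
    normal: 3.0
  prosocial:
    borderline: 5.0
    direction: low_worse
    normal: 6.0
  social:
    borderline: 5.0
    direction: high_worse
    normal: 3.0
  total:
    borderline: 19.0
    direction: high_worse
    normal: 15.0
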