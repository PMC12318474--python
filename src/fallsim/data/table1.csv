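strategy,incremental_public_cost,incremental_societal_qalys
UC,0,0.0
R,5609678,2371.6
SR,54293886,9915.1
R+SR,60993792,12413.0
P,246878182,10386.3
R+P,249448665,12230.0
P+SR,280980595,17319.5
RC,284401514,18934.3
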