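# Body-segment length proportions (geometry only), percent of stature.
# Classical stature-fraction model; compound segments list their
# constituent fractions, which are realized and rounded one by one.
#
# segment <name>  length <f1> <f2> ...
# width   <name>  <fraction>
segment head_neck_trunk       length 13 5.2 28.8
segment left_upper_arm        length 18.6
segment left_forearm_hand     length 14.6 10.8
segment left_thigh            length 24.5
segment left_lower_leg_foot   length 24.6 3.9
segment right_upper_arm       length 18.6
segment right_forearm_hand    length 14.6 10.8
segment right_thigh           length 24.5
segment right_lower_leg_foot  length 24.6 3.9
width shoulder_width 25.9
width hip_bone_width 19.1
width foot_length    15.2
width foot_breadth   5.5
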