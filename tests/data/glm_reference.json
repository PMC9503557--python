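{"face_total":{"angle_class":0.1986182081393,"displacement":0.09448937045444,"bite":0.8288683838494,"age_group":0.1749548898048,"gender":0.8458294341207},"nose":{"angle_class":0.8619168989486,"displacement":0.8712990872234,"bite":0.2162349175391,"age_group":0.6077145726384,"gender":0.2961845295345},"upper_cheek":{"angle_class":0.8931948962922,"displacement":0.1527035824045,"bite":0.4953893453539,"age_group":0.3777539481159,"gender":0.801163799455},"lower_cheek":{"angle_class":0.3332679835155,"displacement":0.2564074385761,"bite":0.8414753833839,"age_group":0.9082559453744,"gender":0.6346734147114},"upper_lip":{"angle_class":0.3973013690931,"displacement":0.3214066364983,"bite":0.7938954003165,"age_group":0.4504101062317,"gender":0.7122693844847},"lower_lip":{"angle_class":0.3084623708262,"displacement":0.4015590489911,"bite":0.611280974145,"age_group":0.8804711715869,"gender":0.3010233313955},"both_lips":{"angle_class":0.692604933724,"displacement":0.3607065106943,"bite":0.440000874016,"age_group":0.1612788197534,"gender":0.5107047596652},"chin":{"angle_class":0.02967185519485,"displacement":0.2605808155831,"bite":0.7209974002819,"age_group":0.65240811203,"gender":6.078394804021e-05}}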