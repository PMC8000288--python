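population,group,method,score,count
expert_1,expert,nearest,1,3
expert_1,expert,nearest,2,2
expert_1,expert,nearest,3,0
expert_1,expert,nearest,4,0
expert_1,expert,bilinear,1,5
expert_1,expert,bilinear,2,0
expert_1,expert,bilinear,3,0
expert_1,expert,bilinear,4,0
expert_1,expert,bicubic,1,3
expert_1,expert,bicubic,2,2
expert_1,expert,bicubic,3,0
expert_1,expert,bicubic,4,0
expert_1,expert,lanczos,1,1
expert_1,expert,lanczos,2,4
expert_1,expert,lanczos,3,0
expert_1,expert,lanczos,4,0
expert_1,expert,srcnn,1,1
expert_1,expert,srcnn,2,2
expert_1,expert,srcnn,3,2
expert_1,expert,srcnn,4,0
expert_1,expert,srgan,1,0
expert_1,expert,srgan,2,2
expert_1,expert,srgan,3,2
expert_1,expert,srgan,4,1
expert_2,expert,nearest,1,4
expert_2,expert,nearest,2,1
expert_2,expert,nearest,3,0
expert_2,expert,nearest,4,0
expert_2,expert,bilinear,1,2
expert_2,expert,bilinear,2,1
expert_2,expert,bilinear,3,2
expert_2,expert,bilinear,4,0
expert_2,expert,bicubic,1,1
expert_2,expert,bicubic,2,4
expert_2,expert,bicubic,3,0
expert_2,expert,bicubic,4,0
expert_2,expert,lanczos,1,0
expert_2,expert,lanczos,2,3
expert_2,expert,lanczos,3,2
expert_2,expert,lanczos,4,0
expert_2,expert,srcnn,1,0
expert_2,expert,srcnn,2,2
expert_2,expert,srcnn,3,3
expert_2,expert,srcnn,4,0
expert_2,expert,srgan,1,0
expert_2,expert,srgan,2,0
expert_2,expert,srgan,3,2
expert_2,expert,srgan,4,3
expert_3,expert,nearest,1,2
expert_3,expert,nearest,2,2
expert_3,expert,nearest,3,1
expert_3,expert,nearest,4,0
expert_3,expert,bilinear,1,4
expert_3,expert,bilinear,2,1
expert_3,expert,bilinear,3,0
expert_3,expert,bilinear,4,0
expert_3,expert,bicubic,1,3
expert_3,expert,bicubic,2,2
expert_3,expert,bicubic,3,0
expert_3,expert,bicubic,4,0
expert_3,expert,lanczos,1,2
expert_3,expert,lanczos,2,2
expert_3,expert,lanczos,3,1
expert_3,expert,lanczos,4,1
expert_3,expert,srcnn,1,1
expert_3,expert,srcnn,2,3
expert_3,expert,srcnn,3,1
expert_3,expert,srcnn,4,0
expert_3,expert,srgan,1,1
expert_3,expert,srgan,2,2
expert_3,expert,srgan,3,2
expert_3,expert,srgan,4,0
expert_4,expert,nearest,1,0
expert_4,expert,nearest,2,0
expert_4,expert,nearest,3,5
expert_4,expert,nearest,4,0
expert_4,expert,bilinear,1,0
expert_4,expert,bilinear,2,3
expert_4,expert,bilinear,3,2
expert_4,expert,bilinear,4,0
expert_4,expert,bicubic,1,0
expert_4,expert,bicubic,2,3
expert_4,expert,bicubic,3,2
expert_4,expert,bicubic,4,0
expert_4,expert,lanczos,1,0
expert_4,expert,lanczos,2,3
expert_4,expert,lanczos,3,2
expert_4,expert,lanczos,4,0
expert_4,expert,srcnn,1,0
expert_4,expert,srcnn,2,2
expert_4,expert,srcnn,3,1
expert_4,expert,srcnn,4,2
expert_4,expert,srgan,1,0
expert_4,expert,srgan,2,0
expert_4,expert,srgan,3,2
expert_4,expert,srgan,4,3
expert_5,expert,nearest,1,0
expert_5,expert,nearest,2,1
expert_5,expert,nearest,3,2
expert_5,expert,nearest,4,2
expert_5,expert,bilinear,1,0
expert_5,expert,bilinear,2,1
expert_5,expert,bilinear,3,2
expert_5,expert,bilinear,4,2
expert_5,expert,bicubic,1,0
expert_5,expert,bicubic,2,1
expert_5,expert,bicubic,3,2
expert_5,expert,bicubic,4,2
expert_5,expert,lanczos,1,0
expert_5,expert,lanczos,2,1
expert_5,expert,lanczos,3,2
expert_5,expert,lanczos,4,2
expert_5,expert,srcnn,1,0
expert_5,expert,srcnn,2,1
expert_5,expert,srcnn,3,2
expert_5,expert,srcnn,4,2
expert_5,expert,srgan,1,0
expert_5,expert,srgan,2,0
expert_5,expert,srgan,3,3
expert_5,expert,srgan,4,2
experts_all,expert,nearest,1,9
experts_all,expert,nearest,2,6
experts_all,expert,nearest,3,8
experts_all,expert,nearest,4,2
experts_all,expert,bilinear,1,11
experts_all,expert,bilinear,2,6
experts_all,expert,bilinear,3,6
experts_all,expert,bilinear,4,2
experts_all,expert,bicubic,1,7
experts_all,expert,bicubic,2,12
experts_all,expert,bicubic,3,4
experts_all,expert,bicubic,4,2
experts_all,expert,lanczos,1,2
experts_all,expert,lanczos,2,13
experts_all,expert,lanczos,3,7
experts_all,expert,lanczos,4,3
experts_all,expert,srcnn,1,2
experts_all,expert,srcnn,2,10
experts_all,expert,srcnn,3,9
experts_all,expert,srcnn,4,4
experts_all,expert,srgan,1,1
experts_all,expert,srgan,2,4
experts_all,expert,srgan,3,11
experts_all,expert,srgan,4,9
lay_all,lay,nearest,1,41
lay_all,lay,nearest,2,30
lay_all,lay,nearest,3,11
lay_all,lay,nearest,4,3
lay_all,lay,bilinear,1,16
lay_all,lay,bilinear,2,45
lay_all,lay,bilinear,3,20
lay_all,lay,bilinear,4,4
lay_all,lay,bicubic,1,8
lay_all,lay,bicubic,2,39
lay_all,lay,bicubic,3,32
lay_all,lay,bicubic,4,6
lay_all,lay,lanczos,1,5
lay_all,lay,lanczos,2,27
lay_all,lay,lanczos,3,46
lay_all,lay,lanczos,4,7
lay_all,lay,srcnn,1,2
lay_all,lay,srcnn,2,23
lay_all,lay,srcnn,3,49
lay_all,lay,srcnn,4,11
lay_all,lay,srgan,1,2
lay_all,lay,srgan,2,24
lay_all,lay,srgan,3,36
lay_all,lay,srgan,4,23
all_observers,all,nearest,1,50
all_observers,all,nearest,2,36
all_observers,all,nearest,3,19
all_observers,all,nearest,4,5
all_observers,all,bilinear,1,27
all_observers,all,bilinear,2,51
all_observers,all,bilinear,3,26
all_observers,all,bilinear,4,6
all_observers,all,bicubic,1,15
all_observers,all,bicubic,2,51
all_observers,all,bicubic,3,36
all_observers,all,bicubic,4,8
all_observers,all,lanczos,1,7
all_observers,all,lanczos,2,40
all_observers,all,lanczos,3,53
all_observers,all,lanczos,4,10
all_observers,all,srcnn,1,4
all_observers,all,srcnn,2,33
all_observers,all,srcnn,3,58
all_observers,all,srcnn,4,15
all_observers,all,srgan,1,3
all_observers,all,srgan,2,28
all_observers,all,srgan,3,47
all_observers,all,srgan,4,32
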